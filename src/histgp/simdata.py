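"""Synthetic multi-year breeding cohorts and alpha-lattice trial phenotypes.

The generator emulates the structure of a stage-2 wheat yield-testing program:
each crop season contributes a fresh cohort of candidate lines (no candidate
repeats across years) plus a small fixed set of checks shared by every year.
Cohorts are crossed within a rolling parent pool whose membership survives
year-to-year with probability ``0.5 ** (1 / relatedness_halflife)`` —
cohorts Delta years apart share ~``0.5 ** (Delta / halflife)`` of their
parents — and whose retired slots are refilled partly from the latest cohort
and partly by novel donor introductions, so realized genomic relatedness
between cohorts decays with their year gap: the property the
forward-validation analysis feeds on.

Phenotypes are simulated at plot level under the stage-one model: subtrials of
``genotypes_per_subtrial`` entries (candidates plus the checks repeated in
every subtrial), ``n_reps`` replications each laid out as resolvable
incomplete blocks, with additive genetic values, year main effects,
genotype-by-year deviations, non-genomic line deviations, design effects and
heterogeneous per-year residual noise.

All randomness flows from one master seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DesignError
from .genomics import MarkerMatrix, compute_grm

__all__ = [
    "FieldDesign",
    "SimConfig",
    "TrueGenetics",
    "simulate_founders",
    "simulate_breeding_program",
    "simulate_trial_phenotypes",
    "simulate_study",
]


@dataclass
class FieldDesign:
    """Alpha-lattice layout and design-effect variances for one subtrial."""

    genotypes_per_subtrial: int = 60
    n_checks_per_subtrial: int = 6
    n_reps: int = 2
    blocks_per_rep: int = 12
    plots_per_block: int = 5
    var_trial: float = 0.05
    var_rep: float = 0.05
    var_block: float = 0.10

    def __post_init__(self):
        if self.blocks_per_rep * self.plots_per_block != self.genotypes_per_subtrial:
            raise ConfigurationError(
                "blocks_per_rep * plots_per_block must equal genotypes_per_subtrial"
            )
        if min(self.genotypes_per_subtrial, self.n_reps,
               self.blocks_per_rep, self.plots_per_block) <= 0:
            raise ConfigurationError("design counts must be positive")
        if self.n_checks_per_subtrial < 0 or \
                self.n_checks_per_subtrial >= self.genotypes_per_subtrial:
            raise ConfigurationError("invalid number of checks per subtrial")
        for name in ("var_trial", "var_rep", "var_block"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def candidates_per_subtrial(self) -> int:
        return self.genotypes_per_subtrial - self.n_checks_per_subtrial


@dataclass
class SimConfig:
    """Generative configuration for a multi-year breeding program.

    ``lines_per_year`` counts new candidate lines per cohort; the ``n_checks``
    shared checks are additional genotypes present in every year. Default
    sizes mirror a program of ~1,000 lines/year tested in 60-entry subtrials
    (1080 = 20 subtrials x 54 candidates, so the lattice arithmetic closes).
    """

    n_years: int = 10
    lines_per_year: int = 1080
    n_markers: int = 2000
    n_chromosomes: int = 21
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 300
    var_g: float = 0.35
    var_gy: float = 0.30
    var_year: float = 0.40
    var_line: float = 0.05
    var_resid_by_year: tuple | None = None
    relatedness_halflife: float = 2.0
    n_checks: int = 6
    mu: float = 5.0
    missing_rate: float = 0.0
    unrelated_cohorts: bool = False
    n_founders: int | None = None
    n_ancestral_haplotypes: int | None = None
    n_parents_per_cohort: int = 64
    novel_parent_fraction: float = 0.5
    donor_drift: float = 0.05
    field: FieldDesign = dc_field(default_factory=FieldDesign)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_years, self.lines_per_year, self.n_markers,
               self.n_chromosomes, self.n_qtl) <= 0:
            raise ConfigurationError("counts must be positive")
        for name in ("var_g", "var_gy", "var_year", "var_line"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.lines_per_year < self.n_checks:
            raise ConfigurationError("lines_per_year must be >= n_checks")
        if self.n_checks < 0:
            raise ConfigurationError("n_checks must be >= 0")
        if self.relatedness_halflife <= 0:
            raise ConfigurationError("relatedness_halflife must be > 0")
        if self.n_ancestral_haplotypes is not None and self.n_ancestral_haplotypes < 2:
            raise ConfigurationError("need >= 2 ancestral haplotypes")
        if self.n_parents_per_cohort < 2:
            raise ConfigurationError("need >= 2 parents per cohort")
        if self.donor_drift < 0:
            raise ConfigurationError("donor_drift must be >= 0")
        if not 0.0 <= self.novel_parent_fraction <= 1.0:
            raise ConfigurationError("novel_parent_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.var_resid_by_year is None:
            # heterogeneous by default: the stage-two model assumes per-year
            # residual variances, so the generator supplies distinct ones
            self.var_resid_by_year = tuple(
                np.round(np.linspace(0.9, 1.5, self.n_years), 6)
            )
        self.var_resid_by_year = tuple(float(v) for v in self.var_resid_by_year)
        if len(self.var_resid_by_year) != self.n_years:
            raise ConfigurationError("var_resid_by_year must have one entry per year")
        if any(v < 0 for v in self.var_resid_by_year):
            raise ConfigurationError("residual variances must be >= 0")
        if self.n_qtl > self.n_markers:
            raise ConfigurationError("n_qtl cannot exceed n_markers")

    def year_labels(self) -> list:
        """Crop-season style labels Y01 .. Yn (sortable strings)."""
        return [f"Y{t + 1:02d}" for t in range(self.n_years)]

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (counter scheme via CRC32)."""
        tag = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


@dataclass
class TrueGenetics:
    """Simulated truth underlying the phenotypes.

    ``breeding_values`` and ``line_deviations`` are keyed by line id (a
    line's additive value is constant across years by construction);
    ``gy_deviations`` is keyed by (year, gid); ``cohorts`` maps each year
    label to the genotype ids grown that year (candidates + checks).
    """

    breeding_values: pd.Series
    line_deviations: pd.Series
    year_effects: pd.Series
    gy_deviations: pd.Series
    cohorts: dict
    check_ids: list

    def breeding_value(self, year, gid) -> float:
        return float(self.breeding_values[gid])

    def gy_deviation(self, year, gid) -> float:
        return float(self.gy_deviations[(year, gid)])


# ---------------------------------------------------------------------------
# founders and cohorts
# ---------------------------------------------------------------------------

def _draw_founder_haplotypes(rng, n, config, n_loci=None):
    n_loci = config.n_markers if n_loci is None else n_loci
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_loci)
    hap_a = (rng.random((n, n_loci)) < p).astype(np.int8)
    hap_b = (rng.random((n, n_loci)) < p).astype(np.int8)
    return hap_a, hap_b, p


def _draw_ld_founders(rng, n, config, n_loci, chrom_slices):
    """Founder haplotypes, optionally as one-crossover mosaics of a limited
    ancestral haplotype pool (``n_ancestral_haplotypes``), which adds
    population-wide linkage disequilibrium; by default founders are drawn in
    linkage equilibrium and all marker-QTL association downstream arises
    from cosegregation within the simulated pedigree."""
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_loci)
    n_anc = config.n_ancestral_haplotypes
    if n_anc is None:
        hap_a = (rng.random((n, n_loci)) < p).astype(np.int8)
        hap_b = (rng.random((n, n_loci)) < p).astype(np.int8)
        return hap_a, hap_b, p
    anc = (rng.random((n_anc, n_loci)) < p).astype(np.int8)

    def mosaic(k):
        out = np.empty((k, n_loci), dtype=np.int8)
        for i in range(k):
            a, b = rng.choice(n_anc, size=2, replace=False)
            out[i] = _gamete(rng, anc[a], anc[b], chrom_slices)
        return out

    return mosaic(n), mosaic(n), p


def _chrom_assignment(n_loci, n_chromosomes):
    chrom = np.array_split(np.arange(n_loci), n_chromosomes)
    chrom_id = np.concatenate([np.full(len(ix), c + 1) for c, ix in enumerate(chrom)])
    pos = np.concatenate([np.arange(1, len(ix) + 1) for ix in chrom])
    edges = np.concatenate([[0], np.cumsum([len(ix) for ix in chrom])])
    slices = list(zip(edges[:-1], edges[1:]))
    return chrom_id, pos, slices


def _marker_table(config, chrom_id=None, pos=None) -> pd.DataFrame:
    if chrom_id is None:
        chrom_id, pos, _ = _chrom_assignment(config.n_markers, config.n_chromosomes)
    names = [f"M{j + 1:05d}" for j in range(len(chrom_id))]
    return pd.DataFrame({"chrom": chrom_id, "pos": pos}, index=names)


def simulate_founders(n_founders: int, config: SimConfig) -> MarkerMatrix:
    """Biallelic founder genotypes in Hardy–Weinberg proportions.

    Per-marker allele frequencies are drawn uniformly from ``maf_range``;
    markers are assigned to chromosomes in contiguous blocks.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least 2 founders")
    rng = config.rng("founders")
    hap_a, hap_b, _ = _draw_founder_haplotypes(rng, n_founders, config)
    dosage = (hap_a + hap_b).astype(float)
    ids = np.array([f"F{i + 1:05d}" for i in range(n_founders)], dtype=object)
    return MarkerMatrix(ids=ids, dosage=dosage, markers=_marker_table(config))


def _gamete(rng, hap_a, hap_b, chrom_slices):
    """One crossover per chromosome at a uniform marker boundary."""
    out = np.empty_like(hap_a)
    for lo, hi in chrom_slices:
        cx = rng.integers(lo, hi + 1)
        if rng.random() < 0.5:
            out[lo:cx] = hap_a[lo:cx]
            out[cx:hi] = hap_b[cx:hi]
        else:
            out[lo:cx] = hap_b[lo:cx]
            out[cx:hi] = hap_a[cx:hi]
    return out


def simulate_breeding_program(config: SimConfig):
    """Simulate cohorts, checks and the true genetic model.

    Returns ``(markers, truth)`` where ``markers`` holds one row per distinct
    genotype (candidates labelled with their cohort year, checks with year
    ``None``) and ``truth`` is a :class:`TrueGenetics`.

    Each cohort is produced by crossing random pairs from a rolling pool of
    ``n_parents_per_cohort`` parents; offspring are formed by per-chromosome
    recombination of parental gametes. Pool membership survives from one year
    to the next with probability ``0.5 ** (1 / relatedness_halflife)`` and
    retired slots are refilled from the latest cohort or by novel donor
    introductions (``novel_parent_fraction``), so parent reuse — and with it
    realized relatedness — decays across years. With
    ``unrelated_cohorts=True`` every cohort is drawn fresh from the founder
    allele frequencies instead (negative control: no shared ancestry beyond
    the checks).

    The ``n_qtl`` causal loci are simulated alongside the panel (linked, on
    the same chromosomes) but are NOT part of the returned marker matrix:
    markers tag the QTL through cosegregation and realized relatedness, as
    with a real genotyping panel, not by containing the causal variants.
    """
    rng = config.rng("program")
    n_founders = config.n_founders or max(config.lines_per_year, 50)
    n_loci = config.n_markers + config.n_qtl
    chrom_id, pos, chrom_slices = _chrom_assignment(n_loci, config.n_chromosomes)
    hap_a0, hap_b0, founder_p = _draw_ld_founders(
        config.rng("founders"), n_founders, config, n_loci, chrom_slices
    )
    qtl_idx = np.sort(config.rng("qtl-loci").choice(n_loci, size=config.n_qtl,
                                                    replace=False))
    panel_idx = np.setdiff1d(np.arange(n_loci), qtl_idx)

    cohort_dosages, cohort_ids = [], []
    year_labels = config.year_labels()
    # Rolling crossing-parent pool: membership survives from one year to the
    # next with probability 0.5 ** (1 / halflife), so cohorts Delta years
    # apart share a fraction ~0.5 ** (Delta / halflife) of their parents —
    # this sets the pace of relatedness decay. Retired slots are refilled
    # partly from the latest cohort and partly by novel introductions from
    # an external donor pool whose allele frequencies random-walk over the
    # years (germplasm turnover makes distant cohorts diverge).
    n_par = min(config.n_parents_per_cohort, n_founders)
    survive = 0.5 ** (1.0 / config.relatedness_halflife)
    donor_p = founder_p.copy()
    sel = rng.choice(n_founders, size=n_par, replace=False)
    pool_a = hap_a0[sel].copy()
    pool_b = hap_b0[sel].copy()
    prev_a = prev_b = None

    for t, year in enumerate(year_labels, start=1):
        n = config.lines_per_year
        if t > 1 and config.donor_drift > 0:
            step = rng.normal(0.0, np.sqrt(config.donor_drift
                                           * donor_p * (1.0 - donor_p)))
            donor_p = np.clip(donor_p + step, 0.02, 0.98)
        if config.unrelated_cohorts:
            ha = (rng.random((n, n_loci)) < founder_p).astype(np.int8)
            hb = (rng.random((n, n_loci)) < founder_p).astype(np.int8)
        else:
            if t > 1:
                retire = np.where(rng.random(n_par) >= survive)[0]
                for i in retire:
                    if rng.random() < config.novel_parent_fraction:
                        pool_a[i] = rng.random(n_loci) < donor_p
                        pool_b[i] = rng.random(n_loci) < donor_p
                    else:
                        j = rng.integers(len(prev_a))
                        pool_a[i] = prev_a[j]
                        pool_b[i] = prev_b[j]
            ha = np.empty((n, n_loci), dtype=np.int8)
            hb = np.empty((n, n_loci), dtype=np.int8)
            for i in range(n):
                pa, pb = rng.choice(n_par, size=2, replace=False)
                ha[i] = _gamete(rng, pool_a[pa], pool_b[pa], chrom_slices)
                hb[i] = _gamete(rng, pool_a[pb], pool_b[pb], chrom_slices)
            prev_a, prev_b = ha, hb
        cohort_dosages.append((ha + hb).astype(float))
        cohort_ids.append(np.array(
            [f"{year}_L{i + 1:04d}" for i in range(n)], dtype=object))

    # checks: fixed founder genotypes, identical in every year
    check_rows = np.arange(config.n_checks)
    check_dosage = (hap_a0[check_rows] + hap_b0[check_rows]).astype(float)
    check_ids = [f"CHK{i + 1:02d}" for i in range(config.n_checks)]

    ids = np.concatenate(cohort_ids + [np.array(check_ids, dtype=object)])
    full_dosage = np.vstack(cohort_dosages + [check_dosage])
    years = np.concatenate(
        [np.full(config.lines_per_year, y, dtype=object) for y in year_labels]
        + [np.full(config.n_checks, None, dtype=object)]
    )
    panel_dosage = full_dosage[:, panel_idx]
    if config.missing_rate > 0:
        mask = config.rng("missingness").random(panel_dosage.shape) < config.missing_rate
        panel_dosage = np.where(mask, np.nan, panel_dosage)
    markers = MarkerMatrix(
        ids=ids, dosage=panel_dosage,
        markers=_marker_table(config, chrom_id[panel_idx], pos[panel_idx]),
        years=years,
    )

    truth = _draw_true_genetics(
        config, markers, qtl_dosage=full_dosage[:, qtl_idx],
        founder_qtl=(hap_a0 + hap_b0)[:, qtl_idx],
        check_ids=check_ids, year_labels=year_labels)
    return markers, truth


def _draw_true_genetics(config, markers, qtl_dosage, founder_qtl, check_ids,
                        year_labels):
    rng_q = config.rng("qtl-effects")
    effects = rng_q.normal(size=config.n_qtl)
    founder_score = founder_qtl.astype(float) @ effects
    sd = founder_score.std()
    scale = np.sqrt(config.var_g) / sd if sd > 0 else 0.0
    effects = effects * scale
    center = founder_score.mean() * scale

    g = qtl_dosage @ effects - center
    breeding_values = pd.Series(g, index=markers.ids)

    rng_l = config.rng("line-dev")
    line_dev = pd.Series(
        rng_l.normal(0.0, np.sqrt(config.var_line), size=len(markers.ids)),
        index=markers.ids,
    )
    rng_y = config.rng("year-effects")
    year_eff = pd.Series(
        rng_y.normal(0.0, np.sqrt(config.var_year), size=config.n_years),
        index=year_labels,
    )

    cohorts = {}
    for y in year_labels:
        cand = [g_ for g_, yy in zip(markers.ids, markers.years) if yy == y]
        cohorts[y] = list(cand) + list(check_ids)

    # G x Y deviations: within a year ~ N(0, var_gy * G_cohort), independent
    # across years (zero covariance between different years, matching the
    # Hadamard-kernel assumption of the stage-two model)
    rng_gy = config.rng("gy")
    keys, vals = [], []
    for y in year_labels:
        ids_y = cohorts[y]
        if config.var_gy > 0:
            sub = markers.subset(ids=ids_y)
            sub = MarkerMatrix(ids=sub.ids, dosage=np.nan_to_num(sub.dosage),
                               markers=sub.markers, years=sub.years)
            gmat = compute_grm(sub).values
            cov = config.var_gy * gmat + 1e-8 * np.eye(len(ids_y))
            chol = np.linalg.cholesky(cov)
            dev = chol @ rng_gy.normal(size=len(ids_y))
        else:
            dev = np.zeros(len(ids_y))
        keys.extend((y, g_) for g_ in ids_y)
        vals.extend(dev)
    gy = pd.Series(vals, index=pd.MultiIndex.from_tuples(keys, names=["year", "gid"]))

    return TrueGenetics(
        breeding_values=breeding_values,
        line_deviations=line_dev,
        year_effects=year_eff,
        gy_deviations=gy,
        cohorts=cohorts,
        check_ids=list(check_ids),
    )


# ---------------------------------------------------------------------------
# trial phenotypes
# ---------------------------------------------------------------------------

def simulate_trial_phenotypes(cohort: MarkerMatrix, truth: TrueGenetics,
                              field: FieldDesign, year, seed: int,
                              env: str = "E1", mu: float | None = None,
                              var_resid: float | None = None,
                              config: SimConfig | None = None) -> pd.DataFrame:
    """Plot-level phenotypes for one year x selection environment.

    ``cohort`` must contain the year's candidates plus the checks (ids in
    ``truth.check_ids``); candidates are partitioned into subtrials of
    ``field.candidates_per_subtrial`` and every check appears once per
    replication in every subtrial. Each plot value is

        mu + g_i + Yg_iy + Y_y + L_i + trial + rep(trial) + block(rep, trial) + eps

    with ``eps ~ N(0, var_resid)``.
    """
    if config is not None:
        if mu is None:
            mu = config.mu
        if var_resid is None:
            year_ix = config.year_labels().index(year)
            var_resid = config.var_resid_by_year[year_ix]
    if mu is None:
        mu = 0.0
    if var_resid is None:
        raise ConfigurationError("var_resid (or config) must be supplied")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(f"{year}|{env}".encode())])
    )
    check_set = set(truth.check_ids)
    candidates = [g for g in cohort.ids if g not in check_set]
    checks = [g for g in cohort.ids if g in check_set]
    if len(checks) != field.n_checks_per_subtrial:
        raise DesignError(
            f"cohort carries {len(checks)} checks, design expects "
            f"{field.n_checks_per_subtrial}"
        )
    per_trial = field.candidates_per_subtrial
    if len(candidates) % per_trial != 0:
        raise DesignError(
            f"{len(candidates)} candidates not divisible into subtrials of {per_trial}"
        )
    n_trials = len(candidates) // per_trial
    order = rng.permutation(len(candidates))

    y_eff = float(truth.year_effects[year])
    g_map = truth.breeding_values.to_dict()
    l_map = truth.line_deviations.to_dict()
    gy_year = truth.gy_deviations.xs(year, level="year").to_dict()

    sd_t = np.sqrt(field.var_trial)
    sd_r = np.sqrt(field.var_rep)
    sd_b = np.sqrt(field.var_block)
    sd_e = np.sqrt(var_resid)
    rows = []
    for t in range(n_trials):
        tlab = f"T{t + 1:02d}"
        t_eff = rng.normal(0.0, sd_t)
        entries = [candidates[i] for i in
                   order[t * per_trial:(t + 1) * per_trial]] + checks
        base = [mu + g_map[g] + gy_year[g] + y_eff + l_map[g] + t_eff
                for g in entries]
        for r in range(field.n_reps):
            rlab = f"R{r + 1}"
            r_eff = rng.normal(0.0, sd_r)
            layout = rng.permutation(len(entries))
            b_effs = rng.normal(0.0, sd_b, field.blocks_per_rep)
            eps = rng.normal(0.0, sd_e, len(entries))
            for pos, e_ix in enumerate(layout):
                b = pos // field.plots_per_block
                rows.append((year, env, tlab, rlab, f"B{b + 1:02d}",
                             pos % field.plots_per_block + 1, entries[e_ix],
                             base[e_ix] + r_eff + b_effs[b] + eps[pos]))
    return pd.DataFrame(
        rows, columns=["year", "env", "trial", "rep", "block", "plot", "gid", "value"]
    )


def simulate_study(config: SimConfig, envs=("E1",)):
    """Full generative study: program + plot phenotypes for every year/env.

    Year effects and G x Y deviations are shared across environments (a
    single-environment analysis is the primary use; multi-env phenotypes
    reuse the same genetic truth with independent field noise).

    Returns ``(markers, truth, plots)`` with ``plots`` one concatenated
    PlotRecords table.
    """
    markers, truth = simulate_breeding_program(config)
    complete = MarkerMatrix(ids=markers.ids, dosage=np.nan_to_num(markers.dosage),
                            markers=markers.markers, years=markers.years)
    frames = []
    for e_ix, env in enumerate(envs):
        for year in config.year_labels():
            cohort = complete.subset(ids=truth.cohorts[year])
            frames.append(simulate_trial_phenotypes(
                cohort, truth, config.field, year,
                seed=config.seed + 7919 * (e_ix + 1),
                env=env, config=config,
            ))
    return markers, truth, pd.concat(frames, ignore_index=True)
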