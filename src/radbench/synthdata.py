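"""Synthetic inputs for the signature-benchmarking pipeline.

Real studies of in-vitro-trained radiosensitivity signatures rest on three
kinds of data: a cell-line training panel with clonogenic SF2 measurements
(NCI60-like), probe-level microarray intensities that must be normalized and
summarized to gene level, and clinical cohorts with right-censored survival
or recurrence outcomes split by radiotherapy status.  This module generates
all three with the statistical structure the downstream analysis assumes, so
every stage of the pipeline is testable without external downloads.

The generators are fully deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import rankdata

OUTCOME_TYPES = ("OS", "FR")

#: Cohort layout mirroring a multi-cohort validation study: two outcomes
#: (overall survival, first recurrence) crossed with radiotherapy status,
#: several cohorts per cell.  Entries are (cohort_id, outcome_type, rt, n).
DEFAULT_COHORT_SPEC = [
    ("gbm_os_rt", "OS", 1, 186),
    ("breast_a_os_rt", "OS", 1, 77),
    ("luad_os_rt", "OS", 1, 65),
    ("gbm_os_nort", "OS", 0, 55),
    ("breast_a_os_nort", "OS", 0, 82),
    ("luad_os_nort", "OS", 0, 364),
    ("breast_b_fr_rt", "FR", 1, 282),
    ("breast_a_fr_rt", "FR", 1, 77),
    ("breast_b_fr_nort", "FR", 0, 62),
    ("breast_a_fr_nort", "FR", 0, 82),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all three generators.

    Parameters
    ----------
    n_genes, n_lines, n_patients_per_cohort, probes_per_gene
        Problem sizes.  ``probes_per_gene`` must be >= 3 so probe-set
        summarization is meaningful.
    frac_prognostic
        Fraction of genes given a nonzero log-hazard coefficient in the
        clinical simulator.  Default 0.15: with the default effect size this
        reproduces the regime in which roughly 12-18% of genes reach p < 0.05
        in univariate Cox scans.
    effect_sd
        SD of the per-gene log-hazard coefficients (per SD of expression).
    censoring_target
        Intended expected censoring fraction in (0, 1); an independent
        exponential censoring rate is solved numerically to achieve it.
    array_scale_sd, array_nonlinearity_amp, probe_affinity_sd, noise_sd
        Probe-level distortion magnitudes on the log2 scale: per-array
        multiplicative offset, amplitude of a per-array smooth nonlinear
        response curve, per-probe affinity spread, and iid measurement noise.
    rt_specific_frac
        Additional fraction of genes whose prognostic effect applies only to
        radiotherapy-treated patients (default 0: effects shared across arms).
    n_factors, factor_var
        Shared latent biological programs (proliferation-like axes of
        covariation).  Every gene loads on ``n_factors`` latent factors with
        loadings drawn once per gene universe (see ``biology_seed``), adding
        ``factor_var`` of expression variance on top of unit noise.  The same
        loadings act in the cell-line panel and the clinical cohorts, which
        is what lets signatures trained in vitro pick up outcome-associated
        programs in the clinic.
    sf2_factor_coef, hazard_factor_coef
        Coefficients of the first latent factor in the SF2 linear predictor
        and in the clinical log hazard.  Both nonzero by default: general
        programs confound the in-vitro endpoint and the clinical outcome, so
        even randomly resampled signatures carry prognostic signal, more so
        the larger they are.  Set ``hazard_factor_coef=0`` (with
        ``frac_prognostic=0``) for a global-null clinical simulator.
    biology_seed
        Seed for the gene-level "biology" (per-gene mean expression and
        factor loadings) shared across generators, so a panel and a cohort
        set describe the same gene universe even when their ``seed`` differs.
    seed
        Fixes every stochastic output bit-for-bit.
    """

    n_genes: int = 1000
    n_lines: int = 60
    n_patients_per_cohort: int = 150
    probes_per_gene: int = 5
    frac_prognostic: float = 0.15
    effect_sd: float = 0.2
    censoring_target: float = 0.5
    array_scale_sd: float = 0.25
    array_nonlinearity_amp: float = 0.3
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.1
    rt_specific_frac: float = 0.0
    n_factors: int = 3
    factor_var: float = 0.1
    sf2_factor_coef: float = 0.6
    hazard_factor_coef: float = 0.3
    biology_seed: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_prognostic", "rt_specific_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_sd", "array_scale_sd", "array_nonlinearity_amp",
                     "probe_affinity_sd", "noise_sd", "factor_var"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0.0 < self.censoring_target < 1.0:
            raise ValueError(
                f"censoring_target must be in (0, 1), got {self.censoring_target}")
        if self.probes_per_gene < 3:
            raise ValueError("probes_per_gene must be >= 3")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CellLinePanel:
    """Expression over cell lines plus one SF2 value per line.

    ``expr`` is a genes x lines log2 matrix; ``sf2`` is the surviving
    fraction at 2 Gy, strictly in (0, 1].
    """

    expr: pd.DataFrame
    sf2: pd.Series

    def __post_init__(self) -> None:
        if self.expr.isna().any().any():
            raise ValueError("panel expression contains missing values")
        if not self.expr.index.is_unique:
            raise ValueError("gene ids must be unique")
        if ((self.sf2 <= 0) | (self.sf2 > 1)).any():
            raise ValueError("sf2 must lie in (0, 1]")

    @property
    def gene_ids(self) -> list:
        return list(self.expr.index)

    @property
    def line_ids(self) -> list:
        return list(self.expr.columns)


@dataclass
class PrognosticTruth:
    """Ground truth of the clinical simulator: which genes carry signal."""

    beta: pd.Series                 # per-gene log HR per SD (shared arms)
    beta_rt: pd.Series              # RT-only additional log HR per SD
    censoring_rate: float

    @property
    def prognostic_genes(self) -> list:
        return list(self.beta.index[self.beta != 0])


@dataclass
class ClinicalCohortSet:
    """Per-patient expression with time/event/RT/cohort annotation.

    ``clinical`` is indexed by sample id with columns cohort_id,
    outcome_type, time, event, rt; ``expr`` is genes x patients.
    """

    expr: pd.DataFrame
    clinical: pd.DataFrame
    covariates: pd.DataFrame | None = None
    truth: PrognosticTruth | None = None

    def __post_init__(self) -> None:
        cl = self.clinical
        if (cl["time"] <= 0).any():
            raise ValueError("follow-up times must be > 0")
        for col in ("event", "rt"):
            if not cl[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        per_cohort = cl.groupby("cohort_id")["outcome_type"].nunique()
        if (per_cohort > 1).any():
            bad = per_cohort.index[per_cohort > 1].tolist()
            raise ValueError(f"cohorts with >1 outcome_type: {bad}")
        if not cl.index.equals(self.expr.columns):
            if set(cl.index) != set(self.expr.columns):
                raise ValueError("clinical table and expression samples differ")
            self.expr = self.expr[cl.index]

    @property
    def sample_ids(self) -> list:
        return list(self.clinical.index)


@dataclass
class ProbeLevelArraySet:
    """Probe x array raw intensities (natural scale) with a probe->gene map."""

    intensities: pd.DataFrame
    probe_to_gene: pd.Series
    truth_expr: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive")
        unmapped = self.intensities.index.difference(self.probe_to_gene.index)
        if len(unmapped):
            raise ValueError(f"probes without gene mapping: {list(unmapped[:5])}")

    @property
    def gene_order(self) -> list:
        return list(pd.unique(self.probe_to_gene.loc[self.intensities.index]))


def gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _biology(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene means and latent-factor loadings, shared across generators."""
    rng = np.random.default_rng(cfg.biology_seed)
    mu = rng.normal(8.0, 2.0, size=cfg.n_genes)
    loadings = rng.normal(0.0, np.sqrt(cfg.factor_var / cfg.n_factors),
                          size=(cfg.n_genes, cfg.n_factors))
    return mu, loadings


def simulate_cell_line_panel(
    cfg: SimulationConfig,
    signature_genes: list[str],
    coefficients,
    intercept: float = 0.0,
    sf2_link: str = "logistic",
) -> CellLinePanel:
    """Simulate an NCI60-like training panel.

    SF2 is generated from the within-line rankings of ``signature_genes``:
    ``lin = intercept + sum_g coef_g * rank_g + N(0, noise_sd)``, pushed
    through the chosen link (``logistic`` -> ``expit``; ``linear`` -> none)
    and clamped to (0.01, 0.99).  The ``linear`` link makes the generating
    model identical to the rank-linear model form, enabling exact closed-loop
    coefficient recovery.  Expression is gene-level log2: per-gene mean
    (N(8, 2^2)) plus unit-variance noise per line.
    """
    cfg.validate()
    genes = gene_ids(cfg.n_genes)
    universe = set(genes)
    for g in signature_genes:
        if g not in universe:
            raise ValueError(f"unknown signature gene: {g}")
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (len(signature_genes),):
        raise ValueError("coefficients must match signature_genes in length")
    if sf2_link not in ("logistic", "linear"):
        raise ValueError(f"unknown sf2_link: {sf2_link}")

    rng = np.random.default_rng(cfg.seed)
    lines = [f"line{i:03d}" for i in range(cfg.n_lines)]
    mu, loadings = _biology(cfg)
    factors = rng.standard_normal((cfg.n_factors, cfg.n_lines))
    expr = (mu[:, None] + loadings @ factors
            + rng.standard_normal((cfg.n_genes, cfg.n_lines)))
    expr = pd.DataFrame(expr, index=genes, columns=lines)

    sub = expr.loc[list(signature_genes)].to_numpy()
    ranks = rankdata(sub, axis=0)  # within-line ranks among signature genes
    lin = intercept + coefficients @ ranks + cfg.sf2_factor_coef * factors[0]
    lin = lin + rng.normal(0.0, cfg.noise_sd, size=cfg.n_lines)
    sf2 = expit(lin) if sf2_link == "logistic" else lin
    sf2 = np.clip(sf2, 0.01, 0.99)
    return CellLinePanel(expr=expr, sf2=pd.Series(sf2, index=lines, name="sf2"))


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with E[fraction censored] = target.

    A patient with event rate lam and independent Exp(c) censoring is
    censored with probability c / (c + lam); average over the realized
    hazards and invert numerically.
    """

    def f(log_c):
        c = np.exp(log_c)
        return np.mean(c / (c + hazards)) - target

    return float(np.exp(brentq(f, -30.0, 30.0)))


def simulate_clinical_cohorts(
    cfg: SimulationConfig,
    cohort_spec: list[tuple] | None = None,
) -> ClinicalCohortSet:
    """Simulate right-censored clinical cohorts with planted prognostic genes.

    A ``frac_prognostic`` subset of genes receives log-hazard coefficients
    beta_g ~ N(0, effect_sd^2), shared between the RT and no-RT arms (plus an
    optional RT-only subset of size ``rt_specific_frac``).  Survival times
    are exponential with rate exp(sum_g beta_g z_g) (baseline rate 1);
    censoring is independent exponential with rate solved so the expected
    censored fraction matches ``censoring_target``.  Ground truth is returned
    in ``.truth``.
    """
    cfg.validate()
    if cohort_spec is None:
        cohort_spec = [(cid, out, rt, cfg.n_patients_per_cohort)
                       for cid, out, rt, _ in DEFAULT_COHORT_SPEC]
    seen = set()
    for cid, out, rt, n in cohort_spec:
        if out not in OUTCOME_TYPES:
            raise ValueError(f"unknown outcome_type {out!r} for cohort {cid}")
        if rt not in (0, 1):
            raise ValueError(f"rt must be 0/1 for cohort {cid}")
        if n < 10:
            raise ValueError(f"cohort {cid} has n={n} < 10")
        if cid in seen:
            raise ValueError(f"duplicate cohort_id {cid}")
        seen.add(cid)

    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids(cfg.n_genes)
    n_total = sum(n for *_, n in cohort_spec)

    n_prog = int(round(cfg.frac_prognostic * cfg.n_genes))
    beta = np.zeros(cfg.n_genes)
    prog_idx = rng.choice(cfg.n_genes, size=n_prog, replace=False)
    beta[prog_idx] = rng.normal(0.0, cfg.effect_sd, size=n_prog)

    beta_rt = np.zeros(cfg.n_genes)
    n_rt = int(round(cfg.rt_specific_frac * cfg.n_genes))
    if n_rt:
        pool = np.setdiff1d(np.arange(cfg.n_genes), prog_idx)
        rt_idx = rng.choice(pool, size=n_rt, replace=False)
        beta_rt[rt_idx] = rng.normal(0.0, cfg.effect_sd, size=n_rt)

    mu, loadings = _biology(cfg)
    factors = rng.standard_normal((cfg.n_factors, n_total))
    z = loadings @ factors + rng.standard_normal((cfg.n_genes, n_total))
    expr = mu[:, None] + z

    sample_ids, cohort_col, outcome_col, rt_col = [], [], [], []
    for cid, out, rt, n in cohort_spec:
        sample_ids += [f"{cid}_s{i:04d}" for i in range(n)]
        cohort_col += [cid] * n
        outcome_col += [out] * n
        rt_col += [rt] * n
    rt_arr = np.asarray(rt_col, dtype=float)

    eta = beta @ z + rt_arr * (beta_rt @ z) + cfg.hazard_factor_coef * factors[0]
    hazards = np.exp(eta)
    event_times = rng.exponential(1.0 / hazards)
    c_rate = _solve_censoring_rate(hazards, cfg.censoring_target)
    censor_times = rng.exponential(1.0 / c_rate, size=n_total)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    clinical = pd.DataFrame(
        {"cohort_id": cohort_col, "outcome_type": outcome_col,
         "time": time, "event": event, "rt": np.asarray(rt_col, dtype=int)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = PrognosticTruth(
        beta=pd.Series(beta, index=genes, name="beta"),
        beta_rt=pd.Series(beta_rt, index=genes, name="beta_rt"),
        censoring_rate=c_rate,
    )
    expr = pd.DataFrame(expr, index=genes, columns=clinical.index)
    return ClinicalCohortSet(expr=expr, clinical=clinical, truth=truth)


def expression_to_probes(truth_expr: pd.DataFrame,
                         cfg: SimulationConfig) -> ProbeLevelArraySet:
    """Expand gene-level truth into distorted probe-level intensities.

    intensity(probe p of gene g, array a)
        = 2 ** (truth(g, a) + affinity_p + s_a + f_a(truth(g, a)) + eps)

    with probe affinities N(0, probe_affinity_sd^2), array offsets
    s_a ~ N(0, array_scale_sd^2), f_a a random per-array cubic polynomial in
    expression level scaled to amplitude ``array_nonlinearity_amp`` (cubics
    with random coefficients are generically non-monotone, so inter-array
    maps genuinely disagree), and eps ~ N(0, noise_sd^2).
    """
    cfg.validate()
    X = truth_expr.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("truth expression contains non-finite values")
    rng = np.random.default_rng(cfg.seed)
    n_genes, n_arrays = X.shape
    ppg = cfg.probes_per_gene

    probe_ids = [f"{g}_p{j}" for g in truth_expr.index for j in range(ppg)]
    probe_to_gene = pd.Series(
        np.repeat(truth_expr.index.to_numpy(), ppg),
        index=pd.Index(probe_ids, name="probe_id"), name="gene_id")

    affinity = rng.normal(0.0, cfg.probe_affinity_sd, size=len(probe_ids))
    s = rng.normal(0.0, cfg.array_scale_sd, size=n_arrays)

    lo, hi = X.min(), X.max()
    mid, half = (lo + hi) / 2.0, max((hi - lo) / 2.0, 1e-12)
    u = (X - mid) / half  # in [-1, 1]
    coefs = rng.standard_normal((n_arrays, 3))
    grid = np.linspace(-1.0, 1.0, 201)
    gpow = np.vstack([grid, grid**2, grid**3])
    fa = np.zeros_like(X)
    if cfg.array_nonlinearity_amp > 0:
        for a in range(n_arrays):
            raw_grid = coefs[a] @ gpow
            scale = cfg.array_nonlinearity_amp / max(np.abs(raw_grid).max(), 1e-12)
            fa[:, a] = scale * (coefs[a, 0] * u[:, a]
                                + coefs[a, 1] * u[:, a] ** 2
                                + coefs[a, 2] * u[:, a] ** 3)

    log_probe = (np.repeat(X + s[None, :] + fa, ppg, axis=0)
                 + affinity[:, None]
                 + rng.normal(0.0, cfg.noise_sd, size=(len(probe_ids), n_arrays)))
    intensities = pd.DataFrame(2.0 ** log_probe, index=probe_ids,
                               columns=truth_expr.columns)
    return ProbeLevelArraySet(intensities=intensities,
                              probe_to_gene=probe_to_gene,
                              truth_expr=truth_expr.copy())


def simulate_gene_sets(
    universe: list[str],
    n_sets: int = 50,
    min_size: int = 10,
    max_size: int = 60,
    seed: int = 0,
    special_sets: dict[str, list[str]] | None = None,
):
    """Random gene-set collection standing in for an ontology.

    Sets are uniform draws without replacement from ``universe``; entries of
    ``special_sets`` (e.g. the planted prognostic genes) are added verbatim
    so enrichment power experiments have a known positive control.
    """
    from .enrichment import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"set{i:03d}"] = list(members)
    if special_sets:
        for name, members in special_sets.items():
            if name in sets:
                raise ValueError(f"duplicate set name {name}")
            sets[name] = list(members)
    return GeneSetCollection(sets=sets, universe=universe)
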