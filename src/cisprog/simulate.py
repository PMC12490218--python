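"""Synthetic hashed treatment/control single-cell experiments with planted truth.

The generator emulates a cell-line cisplatin exposure design: a small number of
cell-line archetypes, each profiled in several replicate experiments, every
experiment containing untreated cells (control and vehicle) plus cells treated
at three dose levels (10%, 50% and 200% of the IC50) for two durations (12 h
and 24 h).  Expression is driven by a low-rank log-linear model:

    log mu[i, g] = baseline[g]
                 + sum_p loadings[g, p] * activity[i, p]
                 + strength * dose_frac * (duration / 24 h)
                   * responsiveness[i] * response[g]

where the programs ``p`` comprise two cell-cycle programs (S, G2/M), one
response *modulator* program whose per-cell activity scales the magnitude of
the treatment-induced shift, and a configurable number of nuisance programs.
Counts are drawn from a negative binomial (gamma-Poisson) with a shared
dispersion and lognormal library-size variation.  Every bundle carries the
planted ground truth so downstream stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "SimConfig",
    "GroundTruth",
    "ExperimentBundle",
    "generate_experiment",
    "generate_replicate_set",
]

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class Condition:
    """One hashed treatment condition."""

    label: str
    dose_fraction: float  # fraction of IC50; 0 for control/vehicle
    duration_h: float  # hours of exposure; 0 for control/vehicle

    def __post_init__(self) -> None:
        if self.dose_fraction < 0 or self.duration_h < 0:
            raise ValueError("dose fraction and duration must be non-negative")

    @property
    def treated(self) -> bool:
        return self.dose_fraction > 0


def default_conditions() -> tuple[Condition, ...]:
    """Control + vehicle + 3 doses x 2 durations (the hashed design)."""
    doses = (0.1, 0.5, 2.0)
    durations = (12.0, 24.0)
    conds = [Condition("control", 0.0, 0.0), Condition("vehicle", 0.0, 0.0)]
    for t in durations:
        for d in doses:
            conds.append(Condition(f"cis{int(d * 100)}_{int(t)}h", d, t))
    return tuple(conds)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults give 8 conditions x 75 cells = 600 cells per experiment on a
    2,000-gene panel, with 2 archetypes x 5 replicates = 10 experiments.
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 75
    cell_line_archetypes: int = 2
    replicates_per_archetype: int = 5
    conditions: tuple[Condition, ...] = field(default_factory=default_conditions)
    n_noise_programs: int = 5
    modulator_link_strength: float = 1.5
    nb_dispersion: float = 0.1
    libsize_lognormal_sigma: float = 0.35
    seed: int = 0
    # shape parameters of the generative model
    program_support: int = 100  # genes carrying each program
    program_activity_sd: float = 6.0  # cell-to-cell sd of program activity
    response_strength: float = 0.2  # ln-scale shift per unit dose*(t/24h)
    phase_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    baseline_log_sd: float = 1.0
    target_counts_per_cell: float = 10000.0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.conditions:
            raise ValueError("condition list must not be empty")
        if self.n_cells_per_condition < 2:
            raise ValueError("need at least 2 cells per condition")
        if self.modulator_link_strength < 0:
            raise ValueError("modulator_link_strength must be >= 0")
        if self.libsize_lognormal_sigma < 0:
            raise ValueError("libsize_lognormal_sigma must be >= 0")
        if abs(sum(self.phase_probs) - 1.0) > 1e-9:
            raise ValueError("phase_probs must sum to 1")
        for c in self.conditions:
            if (c.dose_fraction == 0) != (c.duration_h == 0):
                raise ValueError(
                    f"condition {c.label!r}: dose 0 iff duration 0 (control/vehicle)"
                )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted parameters of one experiment (gene x program, cell x program)."""

    program_loadings: pd.DataFrame  # genes x programs, unit-norm columns
    cell_activities: pd.DataFrame  # cells x programs
    response_vector: np.ndarray  # per-gene treatment-shift direction
    cell_responsiveness: np.ndarray  # per-cell >= 0
    phase_labels: np.ndarray  # per-cell in {G1, S, G2M}

    @property
    def program_names(self) -> list[str]:
        return list(self.program_loadings.columns)


@dataclass
class ExperimentBundle:
    """One hashed experiment: counts, per-cell metadata, optional truth."""

    counts: np.ndarray  # cells x genes, non-negative integers
    cell_meta: pd.DataFrame  # cell_id, condition, dose_fraction, duration_h, ...
    gene_ids: list[str]
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_meta)} cells x {len(self.gene_ids)} genes"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def experiment_id(self) -> str:
        row = self.cell_meta.iloc[0]
        return f"A{row['archetype']}_R{row['replicate']}"

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def mask(self, **column_values) -> np.ndarray:
        """Boolean cell mask, e.g. ``mask(dose_fraction=2.0, duration_h=24)``."""
        m = np.ones(self.n_cells, dtype=bool)
        for col, val in column_values.items():
            m &= (self.cell_meta[col] == val).to_numpy()
        return m

    def to_anndata(self):
        """Represent the bundle as an :class:`anndata.AnnData` (counts in X)."""
        import anndata as ad
        from scipy import sparse

        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts),
            obs=self.cell_meta.set_index("cell_id"),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        return adata


def _experiment_seed(config_seed: int, archetype: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config_seed, spawn_key=(archetype, replicate))


def _response_vector(config: SimConfig) -> np.ndarray:
    """Per-gene treatment-shift direction, shared by every archetype.

    The drug acts on the same targets in all cell lines; archetypes differ in
    baseline expression, programs and how strongly each cell responds, not in
    the direction of the induced shift.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2**31 - 1,))
    )
    return rng.normal(size=config.n_genes)


def _archetype_params(config: SimConfig, archetype: int):
    """Gene-level parameters shared by all replicates of one archetype."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(archetype,))
    )
    g = config.n_genes
    baseline = rng.normal(
        np.log(config.target_counts_per_cell / g) - 0.5 * config.baseline_log_sd**2,
        config.baseline_log_sd,
        size=g,
    )

    program_names = ["S", "G2M", "modulator"] + [
        f"noise{k + 1}" for k in range(config.n_noise_programs)
    ]
    n_prog = len(program_names)
    # programs live on adequately expressed genes (upper half of baseline),
    # with disjoint supports so planted programs are mutually orthogonal
    expressed = np.argsort(baseline)[g // 2 :]
    support = min(config.program_support, max(1, expressed.size // max(n_prog, 1)))
    perm = rng.permutation(expressed)
    loadings = np.zeros((g, n_prog))
    for p in range(n_prog):
        idx = perm[p * support : (p + 1) * support]
        vals = (np.abs(rng.normal(size=support)) + 0.5) * rng.choice([-1.0, 1.0], size=support)
        # total-count neutral: programs redistribute the transcriptome rather
        # than change total RNA, so activity does not confound library size
        w = np.exp(baseline[idx])
        vals = vals - w * (vals @ w) / (w @ w)
        loadings[idx, p] = vals / np.linalg.norm(vals)

    response = _response_vector(config)
    return baseline, pd.DataFrame(loadings, columns=program_names), response


def generate_experiment(
    config: SimConfig,
    archetype: int = 0,
    replicate: int = 0,
    seed: Optional[int] = None,
) -> ExperimentBundle:
    """Simulate one hashed experiment for (archetype, replicate).

    Deterministic given ``(config, archetype, replicate, seed)``; when ``seed``
    is None the cell-level stream is derived from ``config.seed`` so that
    replicates are independent while archetype-level gene parameters
    (baselines, program loadings, response vector) are shared.
    """
    baseline, loadings_df, response = _archetype_params(config, archetype)
    loadings = loadings_df.to_numpy()
    program_names = list(loadings_df.columns)
    n_prog = len(program_names)

    if seed is None:
        ss = _experiment_seed(config.seed, archetype, replicate)
    else:
        ss = np.random.SeedSequence(entropy=int(seed))
    rng = np.random.default_rng(ss)

    n_cond = len(config.conditions)
    n_cells = n_cond * config.n_cells_per_condition
    g = config.n_genes

    # per-cell condition metadata, grouped by condition
    labels = np.repeat([c.label for c in config.conditions], config.n_cells_per_condition)
    dose = np.repeat([c.dose_fraction for c in config.conditions], config.n_cells_per_condition)
    dur = np.repeat([c.duration_h for c in config.conditions], config.n_cells_per_condition)

    # program activities; per-program strengths are spread out (cell cycle
    # strongest, nuisance programs progressively weaker) so the planted
    # covariance spectrum is non-degenerate, as in real data
    phases = rng.choice(PHASES, size=n_cells, p=config.phase_probs)
    activities = np.zeros((n_cells, n_prog))
    sd = config.program_activity_sd
    for name, phase, mult in (("S", "S", 1.2), ("G2M", "G2M", 0.95)):
        j = program_names.index(name)
        in_phase = phases == phase
        m = mult * sd
        activities[in_phase, j] = np.abs(rng.normal(m, 0.25 * m, size=in_phase.sum()))
    j_mod = program_names.index("modulator")
    mod_z = rng.normal(size=n_cells)
    activities[:, j_mod] = sd * mod_z
    for k in range(config.n_noise_programs):
        j = program_names.index(f"noise{k + 1}")
        activities[:, j] = rng.normal(0.0, 0.6 * 0.6**k * sd, size=n_cells)

    # responsiveness: bounded logistic link to standardized modulator activity,
    # strictly increasing, range (0, 2), value 1 at the median cell
    link = config.modulator_link_strength
    responsiveness = 2.0 / (1.0 + np.exp(-link * mod_z))

    dose_scale = dose * (dur / 24.0)  # zero for control/vehicle
    log_mu = (
        baseline[None, :]
        + activities @ loadings.T
        + config.response_strength
        * (dose_scale * responsiveness)[:, None]
        * response[None, :]
    )

    lib = np.exp(rng.normal(0.0, config.libsize_lognormal_sigma, size=n_cells))
    mu = lib[:, None] * np.exp(log_mu)

    # gamma-Poisson = negative binomial with var = mu + alpha * mu^2
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = [f"A{archetype}_R{replicate}_C{i:05d}" for i in range(n_cells)]
    cell_meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "condition": labels,
            "dose_fraction": dose,
            "duration_h": dur,
            "replicate": replicate,
            "archetype": archetype,
            "phase": phases,
        }
    )
    gene_ids = [f"gene{i:04d}" for i in range(g)]

    truth = GroundTruth(
        program_loadings=loadings_df.set_axis(gene_ids, axis=0),
        cell_activities=pd.DataFrame(activities, columns=program_names, index=cell_ids),
        response_vector=response,
        cell_responsiveness=responsiveness,
        phase_labels=phases,
    )
    return ExperimentBundle(counts=counts, cell_meta=cell_meta, gene_ids=gene_ids, ground_truth=truth)


def generate_replicate_set(config: SimConfig) -> list[ExperimentBundle]:
    """All archetype x replicate bundles (default 2 x 5 = 10).

    Replicates of one archetype share gene-level truth (baseline, loadings,
    response vector) but draw independent cells.
    """
    bundles = []
    for a in range(config.cell_line_archetypes):
        for r in range(config.replicates_per_archetype):
            bundles.append(generate_experiment(config, archetype=a, replicate=r))
    return bundles


def expected_log_mean(
    config: SimConfig, bundle: ExperimentBundle
) -> np.ndarray:
    """Noise-free per-cell log mean expression implied by the planted truth.

    Exposes the generative formula (baseline + program effects + scaled
    treatment shift) for verification; excludes library size.
    """
    truth = bundle.ground_truth
    if truth is None:
        raise ValueError("bundle carries no ground truth")
    baseline, loadings_df, response = _archetype_params(
        config, int(bundle.cell_meta["archetype"].iloc[0])
    )
    dose_scale = (
        bundle.cell_meta["dose_fraction"].to_numpy()
        * bundle.cell_meta["duration_h"].to_numpy()
        / 24.0
    )
    return (
        baseline[None, :]
        + truth.cell_activities.to_numpy() @ loadings_df.to_numpy().T
        + config.response_strength
        * (dose_scale * truth.cell_responsiveness)[:, None]
        * response[None, :]
    )
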