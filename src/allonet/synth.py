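"""Synthetic ensemble and feature-table generation with planted structure.

The generator emulates the statistical signatures of a multidomain-kinase
simulation campaign without running molecular dynamics:

* per-residue Gaussian Cα fluctuations around a fixed reference geometry,
* planted intra-region correlation blocks (coherent domain motion),
* planted cross-region "hub" couplings whose strength differs between
  active-like and inactive-like systems — active-like ensembles have
  globally coupled hubs, inactive-like ensembles have the same hubs
  decoupled (fragmented networks),
* class-separated 16-feature tables for the state classifier.

Because the same residue-level correlation matrix is applied independently
to x, y and z, the planted matrix *is* the expected displacement
cross-correlation matrix of the sampled ensemble, which makes every
downstream stage oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DomainMap, Ensemble, StructureModel, SystemEntry, SystemManifest

__all__ = [
    "CouplingSpec",
    "StudyConfig",
    "build_planted_covariance",
    "sample_ensemble",
    "make_reference",
    "default_domain_map",
    "compact_domain_map",
    "generate_study_set",
    "generate_feature_table",
]


@dataclass
class CouplingSpec:
    """Planted correlation structure for one system.

    ``intra_block_corr`` is the within-region correlation, ``hub_cross_corr``
    the correlation of hub residues with residues of *other* regions, and
    ``baseline_corr`` the residual cross-region correlation.  The resulting
    matrix is repaired to the nearest PSD matrix by eigenvalue clipping.
    """

    intra_block_corr: float = 0.85
    hub_residues: tuple[int, ...] = ()
    hub_cross_corr: float = 0.85
    baseline_corr: float = 0.10
    fluctuation_scale: float = 1.0   # Å per axis

    def __post_init__(self) -> None:
        if not 0.0 < self.intra_block_corr < 1.0:
            raise ValueError("intra_block_corr must be in (0, 1)")
        if not 0.0 <= self.baseline_corr < 1.0:
            raise ValueError("baseline_corr must be in [0, 1)")
        if self.hub_residues and not (
            self.baseline_corr <= self.hub_cross_corr <= self.intra_block_corr
        ):
            raise ValueError(
                "require baseline_corr <= hub_cross_corr <= intra_block_corr"
            )
        if self.fluctuation_scale <= 0:
            raise ValueError("fluctuation_scale must be positive")


def build_planted_covariance(domain_map: DomainMap, spec: CouplingSpec) -> np.ndarray:
    """Planted residue correlation matrix over the domain map's selection.

    Entry (i, j) is ``intra_block_corr`` within a region, ``hub_cross_corr``
    across regions when either residue is a hub, and ``baseline_corr``
    otherwise; the diagonal is 1.  If the construction is indefinite it is
    projected to the nearest PSD matrix (eigenvalues clipped at 1e-8) and
    the diagonal renormalised back to 1.
    """
    res_ids = domain_map.res_ids
    labels = domain_map.labels_for(res_ids)
    n = len(res_ids)
    same = labels[:, None] == labels[None, :]
    hub = np.isin(res_ids, np.asarray(spec.hub_residues, dtype=int))
    either_hub = hub[:, None] | hub[None, :]
    corr = np.where(same, spec.intra_block_corr,
                    np.where(either_hub, spec.hub_cross_corr, spec.baseline_corr))
    np.fill_diagonal(corr, 1.0)

    evals = np.linalg.eigvalsh(corr)
    if evals.min() < 1e-8:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 1e-8, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("covariance still indefinite after PSD repair")
    return corr


def make_reference(domain_map: DomainMap, radius: float = 9.0,
                   pitch: float = 6.0, spacing: float = 3.8) -> StructureModel:
    """Cα reference geometry: a solenoid with 3.8 Å spacing.

    The chain winds around a cylinder so successive turns pack against each
    other, giving region–region contacts plausible enough for SASA and
    interface analysis.  Not a physical protein model.
    """
    res_ids = domain_map.res_ids
    n = len(res_ids)
    circ_per_turn = 2 * np.pi * radius
    dtheta = spacing / np.sqrt(radius**2 + (pitch / (2 * np.pi)) ** 2)
    theta = dtheta * np.arange(n)
    coords = np.column_stack([
        radius * np.cos(theta),
        radius * np.sin(theta),
        pitch * theta / (2 * np.pi),
    ])
    return StructureModel(
        coords=coords,
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        res_id=res_ids,
        res_name=np.full(n, "ALA"),
        chain_id=np.full(n, "A"),
        source="synthetic solenoid reference",
    )


def sample_ensemble(covariance: np.ndarray, reference: StructureModel,
                    n_frames: int, seed: int,
                    fluctuation_scale: float = 1.0,
                    system: str = "", replicate: int = 0) -> Ensemble:
    """Sample an ensemble with the given residue displacement correlation.

    Per-axis displacements are zero-mean multivariate normal with the given
    correlation matrix, drawn independently for x, y and z, scaled by
    ``fluctuation_scale`` (Å), and added to the reference Cα positions.
    Frames therefore share the reference frame — no rigid-body drift is
    introduced — and the expected DCCM equals ``covariance``.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames for any fluctuation statistic")
    covariance = np.asarray(covariance, dtype=float)
    ca = reference.ca_only()
    n = covariance.shape[0]
    if ca.n_atoms != n:
        raise ValueError(
            f"covariance dimension {n} != reference residue count {ca.n_atoms}"
        )
    rng = np.random.default_rng(seed)
    # Cholesky with a tiny jitter fallback for semi-definite inputs
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(covariance + 1e-10 * np.eye(n))
    disp = np.empty((n_frames, n, 3))
    for axis in range(3):
        z = rng.standard_normal((n_frames, n))
        disp[:, :, axis] = z @ chol.T
    coords = ca.coords[None] + fluctuation_scale * disp
    return Ensemble(coords, ca.res_id.copy(), system=system, replicate=replicate)


# ---------------------------------------------------------------------------
# study-set design


def default_domain_map() -> DomainMap:
    """Five-region map over residues 60–502 (443 residues), full scale."""
    return DomainMap.from_ranges({
        "SH3": [[60, 126]],
        "SH2": [[127, 230]],
        "L": [[231, 246]],
        "SH1N": [[247, 350]],
        "SH1C": [[351, 502]],
    })


def compact_domain_map() -> DomainMap:
    """An 80-residue five-region map for fast experiments and tests."""
    return DomainMap.from_ranges({
        "SH3": [[1, 16]],
        "SH2": [[17, 32]],
        "L": [[33, 40]],
        "SH1N": [[41, 60]],
        "SH1C": [[61, 80]],
    })


@dataclass
class StudyConfig:
    """Design of a synthetic study set.

    Defaults emulate the study conditions: two active-like systems (apo
    wildtype and ATP-bound wildtype) against four inactive-like systems
    (inhibitor-bound and three mutants), three replicates each, frames
    saved on a uniform interval.  The planted hubs default to the
    interdomain linker residues: in active-like systems the linker couples
    strongly to every domain (a globally integrated network), while in
    inactive-like systems its coupling collapses to baseline, fragmenting
    the network into pure domain modules.

    The default correlation levels (intra 0.90, hub 0.90, baseline 0.72)
    sit where a valid correlation matrix can carry cross-domain hub edges
    above the 0.8 network threshold: a residue coupled above 0.8 to many
    mutually weakly correlated partners is not a realisable correlation
    structure, so strong hubs require a substantially correlated global
    background (as in a concerted active-like state), and PSD repair will
    otherwise silently shrink the planted hub couplings below threshold.
    """

    domain_map: DomainMap = field(default_factory=default_domain_map)
    systems: dict[str, tuple[str, int]] = field(default_factory=lambda: {
        "WT": ("apo", 1),
        "WT-ATP": ("ATP", 1),
        "WT-DAS": ("DAS", 0),
        "E290K-ATP": ("ATP", 0),
        "I364N-ATP": ("ATP", 0),
        "K275A-ATP": ("ATP", 0),
    })
    n_replicates: int = 3
    n_frames: int = 2000
    hub_residues: tuple[int, ...] | None = None   # default: the linker
    rho_intra: float = 0.90
    rho_baseline: float = 0.72
    rho_hub_active: float = 0.90
    rho_hub_inactive: float = 0.72
    fluctuation_scale: float = 1.0

    def __post_init__(self) -> None:
        labels = [lab for _, lab in self.systems.values()]
        if 1 not in labels or 0 not in labels:
            raise ValueError("need at least one active-like and one inactive-like system")
        if self.hub_residues is None:
            self.hub_residues = tuple(
                int(r) for r in self.domain_map.residues_in("L"))
            if not self.hub_residues:
                raise ValueError(
                    "domain map has no linker residues; give hub_residues explicitly")

    def coupling_for(self, label: int) -> CouplingSpec:
        rho_hub = self.rho_hub_active if label == 1 else self.rho_hub_inactive
        return CouplingSpec(
            intra_block_corr=self.rho_intra,
            hub_residues=self.hub_residues,
            hub_cross_corr=rho_hub,
            baseline_corr=self.rho_baseline,
            fluctuation_scale=self.fluctuation_scale,
        )


def compact_study_config(**overrides) -> StudyConfig:
    """Desk-scale study set: 80 residues, 400-frame replicates."""
    defaults = dict(domain_map=compact_domain_map(), n_frames=400)
    defaults.update(overrides)
    return StudyConfig(**defaults)


def generate_study_set(config: StudyConfig, seed: int
                       ) -> tuple[SystemManifest, dict[str, list[Ensemble]],
                                  StructureModel]:
    """Sample the full study set: every system, every replicate.

    Returns the manifest (labels in config order), a dict of per-system
    replicate ensembles, and the shared reference structure.  Per-replicate
    seeds are spawned deterministically from ``seed``.
    """
    reference = make_reference(config.domain_map)
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(config.systems) * config.n_replicates)
    ensembles: dict[str, list[Ensemble]] = {}
    entries: dict[str, SystemEntry] = {}
    i = 0
    for name, (condition, label) in config.systems.items():
        spec = config.coupling_for(label)
        corr = build_planted_covariance(config.domain_map, spec)
        reps = []
        for rep in range(config.n_replicates):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            reps.append(sample_ensemble(
                corr, reference, config.n_frames, seed=child_seed,
                fluctuation_scale=config.fluctuation_scale,
                system=name, replicate=rep,
            ))
        ensembles[name] = reps
        entries[name] = SystemEntry(condition=condition, label=label)
    return SystemManifest(entries), ensembles, reference


# ---------------------------------------------------------------------------
# classifier feature tables


def generate_feature_table(
    n_frames_per_class: int | tuple[int, int],
    effect_size: float,
    seed: int,
    n_features: int = 16,
    n_informative: int = 7,
) -> pd.DataFrame:
    """Gaussian 16-feature table with a planted class separation.

    ``n_informative`` features have class means ``effect_size`` pooled
    standard deviations apart; the remainder are uninformative noise.
    ``n_frames_per_class`` may be a (active, inactive) pair for imbalanced
    designs.  Columns are ``f01..f16`` plus ``label`` (1 = active-like) and
    ``system``.
    """
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    if not 0 <= n_informative <= n_features:
        raise ValueError("n_informative outside [0, n_features]")
    if isinstance(n_frames_per_class, int):
        n_active = n_inactive = n_frames_per_class
    else:
        n_active, n_inactive = n_frames_per_class
    rng = np.random.default_rng(seed)
    shift = np.zeros(n_features)
    shift[:n_informative] = effect_size
    x_active = rng.standard_normal((n_active, n_features)) + shift
    x_inactive = rng.standard_normal((n_inactive, n_features))
    x = np.vstack([x_active, x_inactive])
    y = np.concatenate([np.ones(n_active, int), np.zeros(n_inactive, int)])
    names = [f"f{i + 1:02d}" for i in range(n_features)]
    df = pd.DataFrame(x, columns=names)
    df["label"] = y
    df["system"] = np.where(y == 1, "active-like", "inactive-like")
    # shuffle rows so any later unstratified slicing is harmless
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)
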