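"""Flexibility and geometry descriptors for conformational ensembles.

Superposition is least-squares optimal (Kabsch with proper-rotation
enforcement).  RMSF follows the standard fluctuation convention: frames are
iteratively fitted to the evolving mean structure before deviations are
measured.  Per-domain RMSD uses a global fit by default — deviation of a
domain's atoms after fitting the whole selection — which reads as domain
mobility relative to the core.

Representative structures are PAM (k-medoid) cluster medoids on the pairwise
RMSD matrix, with k chosen by mean silhouette; distribution comparisons use
the two-sided Wilcoxon signed-rank test (paired) or the rank-sum test when
sample sizes differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DomainMap, Ensemble

__all__ = [
    "superpose",
    "superpose_ensemble",
    "rmsd",
    "rmsd_series",
    "rmsf_profile",
    "delta_rmsf",
    "geometry_series",
    "pairwise_rmsd_matrix",
    "pam_kmedoids",
    "representative_structure",
    "compare_distributions",
    "FlexProfile",
    "RMSDSeries",
    "RepresentativeResult",
]


@dataclass
class FlexProfile:
    """Per-residue RMSF (Å) over an ensemble's selection."""
    rmsf: np.ndarray
    res_ids: np.ndarray
    system: str = ""


@dataclass
class RMSDSeries:
    """Per-frame RMSD (Å) against a named reference."""
    values: np.ndarray
    reference: str
    scope: str = "CA"
    domain: str | None = None


@dataclass
class RepresentativeResult:
    frame_index: int
    k: int
    labels: np.ndarray
    silhouette: float
    cluster_sizes: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# superposition


def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred ``mobile`` onto ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # flip the smallest singular direction to enforce det = +1 (no reflection)
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference
        (n, 3) coordinate arrays with matched atoms.
    fit_selection
        Optional index or boolean mask; the transform is fitted on this
        subset but applied to all atoms.

    Returns
    -------
    transformed coordinates and the optimal RMSD over the fit selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    sel = np.arange(len(mobile)) if fit_selection is None else np.asarray(fit_selection)
    m_fit, r_fit = mobile[sel], reference[sel]
    if len(m_fit) < 3:
        raise ValueError("need at least 3 atoms in the fit selection")
    m_cen, r_cen = m_fit.mean(axis=0), r_fit.mean(axis=0)
    a, b = m_fit - m_cen, r_fit - r_cen
    # collinearity check: rank of the centred fit coordinates
    if np.linalg.matrix_rank(b, tol=1e-9) < 2 or np.linalg.matrix_rank(a, tol=1e-9) < 2:
        raise ValueError("degenerate fit: fewer than 3 non-collinear atoms")
    rot = _kabsch_rotation(a, b)
    moved = (mobile - m_cen) @ rot + r_cen
    fitted_rmsd = rmsd(moved[sel], r_fit)
    return moved, fitted_rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def superpose_ensemble(
    ensemble: Ensemble, reference: np.ndarray, fit_selection: np.ndarray | None = None
) -> Ensemble:
    """Superpose every frame onto a reference; returns a new ensemble."""
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        out[f], _ = superpose(ensemble.coords[f], reference, fit_selection)
    return Ensemble(out, ensemble.res_ids, ensemble.system,
                    ensemble.replicate, ensemble.frame_interval)


# ---------------------------------------------------------------------------
# RMSD / RMSF


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray,
    scope: str = "CA",
    domain: str | None = None,
    domain_map: DomainMap | None = None,
    fit: str = "global",
) -> RMSDSeries:
    """Per-frame RMSD against a reference structure.

    ``fit='global'`` (default) fits each frame on the whole selection and
    measures deviation over the domain's residues; ``fit='domain'`` fits on
    the domain itself.  The global-fit mode reports a domain's displacement
    relative to the rest of the structure.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != ensemble.coords.shape[1:]:
        raise ValueError("reference does not match the ensemble selection")
    if domain is not None:
        if domain_map is None:
            raise ValueError("domain restriction requires a domain map")
        labels = domain_map.labels_for(ensemble.res_ids)
        mask = labels == domain
        if not mask.any():
            raise ValueError(f"domain {domain!r} has no residues in the selection")
    else:
        mask = np.ones(ensemble.n_residues, dtype=bool)
    fit_sel = np.flatnonzero(mask) if fit == "domain" else None
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        moved, _ = superpose(ensemble.coords[f], reference, fit_sel)
        values[f] = rmsd(moved[mask], reference[mask])
    return RMSDSeries(values, reference="reference", scope=scope, domain=domain)


def mean_structure(ensemble: Ensemble, n_iter: int = 2) -> tuple[np.ndarray, Ensemble]:
    """Iterated fit-to-mean: returns (mean coords, fitted ensemble).

    Frames are fitted to the current mean, the mean recomputed, ``n_iter``
    times; the fixed point is reached almost immediately for well-behaved
    ensembles.
    """
    fitted = ensemble
    mean = ensemble.coords.mean(axis=0)
    for _ in range(max(1, n_iter)):
        fitted = superpose_ensemble(fitted, mean)
        mean = fitted.coords.mean(axis=0)
    return mean, fitted


def rmsf_profile(ensemble: Ensemble, n_fit_iter: int = 2) -> FlexProfile:
    """Root-mean-square fluctuation per residue after fit-to-mean alignment."""
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mean, fitted = mean_structure(ensemble, n_fit_iter)
    dev = fitted.coords - mean[None]
    msf = np.mean(np.sum(dev * dev, axis=2), axis=0)
    return FlexProfile(np.sqrt(msf), ensemble.res_ids.copy(), ensemble.system)


def delta_rmsf(wt: FlexProfile, mutant: FlexProfile) -> np.ndarray:
    """ΔRMSF = WT − mutant; positive where the wildtype is more flexible."""
    if not np.array_equal(wt.res_ids, mutant.res_ids):
        raise ValueError("profiles are not aligned on the same residues")
    return wt.rmsf - mutant.rmsf


# ---------------------------------------------------------------------------
# geometry


def geometry_series(ensemble: Ensemble, spec: list[dict], domain_map: DomainMap | None = None):
    """Per-frame geometric descriptors.

    Each spec item is a dict with a ``kind`` key:

    * ``{"kind": "distance", "residues": (i, j)}`` — Cα–Cα distance (Å),
    * ``{"kind": "angle", "residues": (i, j, k)}`` — angle at j (degrees),
    * ``{"kind": "centroid_distance", "regions": (A, B)}`` — distance between
      region Cα centroids (Å); needs a domain map,
    * ``{"kind": "centroid_distance", "groups": ([ids], [ids])}`` — explicit
      residue groups.

    Returns a pandas DataFrame with one named column per descriptor.
    """
    import pandas as pd

    coords = ensemble.coords
    cols: dict[str, np.ndarray] = {}
    for item in spec:
        kind = item["kind"]
        if kind == "distance":
            i, j = (ensemble.position_of(r) for r in item["residues"])
            d = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
            name = item.get("name", "d_{}_{}".format(*item["residues"]))
            cols[name] = d
        elif kind == "angle":
            i, j, k = (ensemble.position_of(r) for r in item["residues"])
            v1 = coords[:, i] - coords[:, j]
            v2 = coords[:, k] - coords[:, j]
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            name = item.get("name", "ang_{}_{}_{}".format(*item["residues"]))
            cols[name] = ang
        elif kind == "centroid_distance":
            if "regions" in item:
                if domain_map is None:
                    raise ValueError("region centroids require a domain map")
                groups = [domain_map.residues_in(r) for r in item["regions"]]
                default_name = "dc_{}_{}".format(*item["regions"])
            else:
                groups = [np.asarray(g, dtype=int) for g in item["groups"]]
                default_name = "dc_groups"
            idx = [[ensemble.position_of(int(r)) for r in g] for g in groups]
            if any(len(g) == 0 for g in idx):
                raise ValueError("empty residue group for centroid distance")
            c1 = coords[:, idx[0]].mean(axis=1)
            c2 = coords[:, idx[1]].mean(axis=1)
            cols[item.get("name", default_name)] = np.linalg.norm(c1 - c2, axis=1)
        else:
            raise ValueError(f"unknown descriptor kind {kind!r}")
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# representative structures (PAM medoids)


def pairwise_rmsd_matrix(ensemble: Ensemble, max_frames: int | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs fitted RMSD matrix; optionally on an even frame subsample.

    Returns (distance matrix, frame indices used).
    """
    f_all = np.arange(ensemble.n_frames)
    if max_frames is not None and ensemble.n_frames > max_frames:
        f_all = np.linspace(0, ensemble.n_frames - 1, max_frames).round().astype(int)
        f_all = np.unique(f_all)
    coords = ensemble.coords[f_all]
    n = len(f_all)
    # centre once; pairwise Kabsch on centred coordinates
    centred = coords - coords.mean(axis=1, keepdims=True)
    dmat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            rot = _kabsch_rotation(centred[a], centred[b])
            dmat[a, b] = dmat[b, a] = rmsd(centred[a] @ rot, centred[b])
    return dmat, f_all


def pam_kmedoids(dmat: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """PAM-style k-medoids on a precomputed distance matrix.

    BUILD: greedy medoid seeding minimising total cost.  SWAP: alternate
    assignment and per-cluster medoid updates until stable.  Deterministic.
    Returns (medoid indices, labels).
    """
    n = len(dmat)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    # BUILD
    medoids = [int(np.argmin(dmat.sum(axis=0)))]
    while len(medoids) < k:
        current = np.min(dmat[:, medoids], axis=1)
        gains = np.sum(np.maximum(current[None, :] - dmat, 0.0), axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    # SWAP via alternating update
    for _ in range(max_iter):
        labels = np.argmin(dmat[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = dmat[np.ix_(members, members)].sum(axis=1)
            new[c] = members[int(np.argmin(within))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(dmat[:, medoids], axis=1)
    return medoids, labels


def representative_structure(
    ensemble: Ensemble,
    k_candidates: range | list[int] = range(2, 9),
    max_frames: int | None = 200,
) -> RepresentativeResult:
    """Medoid of the most populated PAM cluster; k chosen by mean silhouette.

    Degenerate (all-identical) ensembles return frame 0 with a warning.
    """
    from sklearn.metrics import silhouette_score

    dmat, frame_idx = pairwise_rmsd_matrix(ensemble, max_frames=max_frames)
    n = len(dmat)
    if np.allclose(dmat, 0.0, atol=1e-10):
        warnings.warn("all frames identical: degenerate clustering, returning frame 0")
        return RepresentativeResult(0, 1, np.zeros(n, dtype=int), float("nan"),
                                    np.array([n]), degenerate=True)
    ks = [k for k in k_candidates if 2 <= k < n]
    if not ks:
        raise ValueError("no feasible k in k_candidates for this frame count")
    best = None
    for k in ks:
        medoids, labels = pam_kmedoids(dmat, k)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dmat, labels, metric="precomputed")
        if best is None or score > best[0]:
            best = (score, k, medoids, labels)
    score, k, medoids, labels = best
    sizes = np.bincount(labels, minlength=k)
    top = int(np.argmax(sizes))
    members = np.flatnonzero(labels == top)
    within = dmat[np.ix_(members, members)].sum(axis=1)
    medoid_local = members[int(np.argmin(within))]
    return RepresentativeResult(
        frame_index=int(frame_idx[medoid_local]), k=k, labels=labels,
        silhouette=float(score), cluster_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# distribution comparison


def compare_distributions(a, b, paired: bool = True) -> tuple[float, float]:
    """Two-sided Wilcoxon comparison of two samples.

    Paired samples use the signed-rank test; unpaired or unequal-length
    samples fall back to the rank-sum (Mann–Whitney) test with a warning.
    All-zero paired differences are a degenerate-test error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) == len(b):
        if np.allclose(a, b):
            raise ValueError("degenerate comparison: all paired differences are zero")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        if paired:
            warnings.warn(
                "unequal sample sizes: falling back to the rank-sum test"
            )
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
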