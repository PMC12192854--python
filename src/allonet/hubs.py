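"""Interface-weighted allosteric-hub scoring.

Combines, per residue r over the N systems of a study:

* rho_r   — Pearson correlation of the betweenness profile b_r across
            systems with the binary activity labels y (1 = active-like);
* M_{r,s} — module-mixing index: 1 − purity of the module containing r in
            system s (the compositional heterogeneity of r's module;
            0 for residues of pure modules);
* mu_r    — mean of M_{r,s} over systems;
* mix_weighted_corr_r = rho_r * mu_r;
* f_r     — interface frequency: fraction of systems in which r sits at an
            interdomain interface (k_r / N);
* interface_weighted_score_r = mix_weighted_corr_r * (1 + f_r).

Residues whose interface-weighted score strictly exceeds 0.5 are flagged
as allosteric hubs: dynamically central in a state-dependent way, members
of region-mixed modules, and enriched at domain interfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import CommunityPartition

__all__ = [
    "centrality_state_correlation",
    "module_mixing",
    "interface_frequency",
    "interface_weighted_score",
    "hub_score_table",
    "HUB_THRESHOLD",
]

#: Strict lower bound for the hub flag.
HUB_THRESHOLD = 0.5


def centrality_state_correlation(B: np.ndarray, y: np.ndarray
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson rho_r of each residue's betweenness profile with the labels.

    ``B`` is (n_residues, n_systems); ``y`` binary with both classes
    present.  Residues with a constant betweenness profile get rho_r = 0
    and are flagged.
    Returns (rho, constant_flag).
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    if B.ndim != 2 or B.shape[1] != len(y):
        raise ValueError("B must be (n_residues, n_systems) aligned with y")
    if y.min() == y.max():
        raise ValueError("labels contain a single class; correlation undefined")
    yc = y - y.mean()
    bc = B - B.mean(axis=1, keepdims=True)
    sb = np.sqrt((bc * bc).sum(axis=1))
    flag = sb <= 1e-300
    denom = np.where(flag, 1.0, sb) * np.sqrt((yc * yc).sum())
    rho = (bc @ yc) / denom
    rho[flag] = 0.0
    return np.clip(rho, -1.0, 1.0), flag


def module_mixing(partitions: list[CommunityPartition], res_ids: np.ndarray,
                  mode: str = "own_module") -> tuple[np.ndarray, np.ndarray]:
    """Module-mixing index M_{r,s} and its mean mu_r over systems.

    ``mode='own_module'`` (default): M_{r,s} = 1 − purity of the module
    containing r in system s — every residue of a region-mixed module
    carries that module's heterogeneity; residues of pure modules (and
    unassigned residues) score 0.

    ``mode='integration_gated'``: M_{r,s} as above but only for residues of
    system s's integration module, 0 elsewhere.  This stricter variant
    rewards recurrent membership in the single most-mixed module; because
    one module is credited per system it under-counts coupling elements
    that Louvain splits across several mixed modules, which is why the
    ungated form is the default.

    Returns (M of shape (n_residues, n_systems), mu of shape (n_residues,)).
    """
    if mode not in ("own_module", "integration_gated"):
        raise ValueError(f"unknown mixing mode {mode!r}")
    res_ids = np.asarray(res_ids, dtype=int)
    n_res, n_sys = len(res_ids), len(partitions)
    if n_sys == 0:
        raise ValueError("no partitions supplied")
    M = np.zeros((n_res, n_sys))
    for s, part in enumerate(partitions):
        if mode == "integration_gated":
            im = part.integration_module
            if im is None:
                continue
            items = [(pos, im) for pos in part.members(im)]
        else:
            items = part.module_of.items()
        for pos, mid in items:
            if pos >= n_res:
                raise ValueError("partition positions exceed the residue set")
            M[pos, s] = 1.0 - part.purity[mid]
    mu = M.mean(axis=1)
    return M, mu


def interface_frequency(interface_sets: list[set[int]], res_ids: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """k_r (system count) and f_r = k_r / N from per-system interface sets."""
    res_ids = np.asarray(res_ids, dtype=int)
    n_sys = len(interface_sets)
    if n_sys == 0:
        raise ValueError("no interface sets supplied")
    k = np.zeros(len(res_ids), dtype=int)
    for iface in interface_sets:
        k += np.isin(res_ids, list(iface))
    return k, k / n_sys


def interface_weighted_score(rho: np.ndarray, mu: np.ndarray, f: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """mix-weighted correlation, interface-weighted score and hub flags.

    score_r = rho_r * mu_r * (1 + f_r); a hub requires score_r > 0.5
    (strict), so a hub always has rho_r > 0.25.
    """
    rho, mu, f = (np.asarray(v, dtype=float) for v in (rho, mu, f))
    if not (rho.shape == mu.shape == f.shape):
        raise ValueError("rho, mu, f must be aligned")
    mix = rho * mu
    score = mix * (1.0 + f)
    return mix, score, score > HUB_THRESHOLD


def hub_score_table(B: np.ndarray, y: np.ndarray,
                    partitions: list[CommunityPartition],
                    interface_sets: list[set[int]],
                    res_ids: np.ndarray,
                    regions: np.ndarray | None = None,
                    consistency: dict[int, float] | None = None,
                    mixing_mode: str = "own_module") -> pd.DataFrame:
    """Full per-residue hub-score table with all intermediate columns.

    The auxiliary ``unified_score`` column (threshold-consistency ×
    mix-weighted correlation) is reported alongside but does not enter the
    interface-weighted score.
    """
    res_ids = np.asarray(res_ids, dtype=int)
    rho, flat = centrality_state_correlation(B, y)
    _, mu = module_mixing(partitions, res_ids, mode=mixing_mode)
    k, f = interface_frequency(interface_sets, res_ids)
    mix, score, is_hub = interface_weighted_score(rho, mu, f)
    df = pd.DataFrame({
        "residue_id": res_ids,
        "rho": rho,
        "rho_constant_flag": flat,
        "mu": mu,
        "mix_weighted_corr": mix,
        "k_interface": k,
        "f_interface": f,
        "interface_weighted_score": score,
        "is_hub": is_hub,
    })
    if regions is not None:
        df.insert(1, "region", np.asarray(regions))
    if consistency is not None:
        df["consistency"] = [consistency.get(int(r), 0.0) for r in res_ids]
        df["unified_score"] = df["consistency"] * mix
    for s in range(B.shape[1]):
        df[f"betweenness_s{s}"] = B[:, s]
    return df
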