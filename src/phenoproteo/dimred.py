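"""Feature-space reduction: MAD ranking and correlated-module hub selection.

High-plex aptamer panels carry thousands of reagents with little biological
variance plus sets of strongly inter-correlated reagents. The reduction has
two stages:

1. keep the top fraction of features by median absolute deviation (MAD,
   computed on the log2 scale before z-scoring);
2. group the survivors into *modules* — connected components of the graph
   with an edge wherever |correlation| meets a threshold — and keep one
   *hub* representative per module.

The default hub rule is deterministic (largest summed |correlation| to
co-members); a seeded random rule supports the hub-randomization
sensitivity analysis. Multiple reduction rounds re-apply module building to
the surviving hub set until no multi-member module remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .matrix import ProteinMatrix


class DimredError(ValueError):
    pass


@dataclass
class FeatureModule:
    """A set of mutually correlated features with one hub representative."""

    module_id: str
    member_feature_ids: tuple[str, ...]
    hub_feature_id: str | None = None
    corr_threshold: float = 0.7
    corr_method: str = "spearman"

    @property
    def size(self) -> int:
        return len(self.member_feature_ids)


@dataclass
class ReductionResult:
    """Outcome of one (possibly multi-round) reduction."""

    selected_feature_ids: list[str]
    modules: list[FeatureModule]
    mad_values: pd.Series
    parameters: dict = field(default_factory=dict)


def _log2_values(matrix: ProteinMatrix) -> pd.DataFrame:
    """MAD and correlations are defined on the log2 scale, pre-z-score."""
    if matrix.transform_state == "raw":
        return np.log2(matrix.values)
    return matrix.values


def mad_select(matrix: ProteinMatrix, fraction: float) -> tuple[list[str], pd.Series]:
    """Keep the ``ceil(fraction * p)`` features of largest MAD.

    MAD(x) = median(|x - median(x)|). Ties break lexicographically by
    feature ID, so the selection is invariant to sample and feature order.
    """
    if not (0 < fraction <= 1):
        raise DimredError(f"fraction must be in (0, 1], got {fraction}")
    vals = _log2_values(matrix)
    med = vals.median(axis=0)
    mad = (vals - med).abs().median(axis=0)
    mad.name = "mad"
    n_keep = int(np.ceil(fraction * matrix.n_features))
    order = sorted(mad.index, key=lambda f: (-mad[f], f))
    return order[:n_keep], mad


def _correlation(values: pd.DataFrame, method: str) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 0, x)
    elif method != "pearson":
        raise DimredError(f"unknown correlation method {method!r}")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = values.columns[np.argmax(sd == 0)]
        raise DimredError(f"zero-variance feature {bad!r}: correlation undefined")
    return np.corrcoef(x, rowvar=False)


def build_modules(
    matrix: ProteinMatrix,
    feature_subset: Sequence[str],
    corr_threshold: float = 0.7,
    corr_method: str = "spearman",
) -> tuple[list[FeatureModule], pd.DataFrame]:
    """Partition ``feature_subset`` into correlation modules.

    Modules are connected components of the graph on the subset with an
    edge where |r| >= threshold, so the partition is independent of feature
    discovery order. Returns the modules (sorted by their lexicographically
    smallest member) and the correlation matrix used.
    """
    feats = list(feature_subset)
    if not feats:
        raise DimredError("empty feature subset")
    if not (0 < corr_threshold < 1):
        raise DimredError(f"corr_threshold must be in (0,1), got {corr_threshold}")
    vals = _log2_values(matrix)[feats]
    corr = _correlation(vals, corr_method)
    adj = (np.abs(corr) >= corr_threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, comp_labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[str]] = {}
    for f, c in zip(feats, comp_labels):
        comps.setdefault(int(c), []).append(f)
    ordered = sorted(comps.values(), key=lambda members: min(members))
    modules = [
        FeatureModule(
            module_id=f"M{i:04d}",
            member_feature_ids=tuple(sorted(members)),
            corr_threshold=corr_threshold,
            corr_method=corr_method,
        )
        for i, members in enumerate(ordered)
    ]
    corr_df = pd.DataFrame(corr, index=feats, columns=feats)
    return modules, corr_df


def select_hubs(
    modules: list[FeatureModule],
    corr: pd.DataFrame,
    mad_values: pd.Series,
    rule: str = "max_connectivity",
    seed: int | None = None,
    randomize_min_size: int = 1,
) -> ReductionResult:
    """Pick one hub per module and emit the reduced feature list.

    ``max_connectivity``: member with the largest sum of |r| to co-members;
    ties go to larger MAD, then lexicographic ID. ``max_mad``: largest MAD,
    ties lexicographic. ``random``: uniform per module from a seeded stream;
    modules smaller than ``randomize_min_size`` fall back to
    max_connectivity (used by the hub-randomization sensitivity analysis,
    which re-draws hubs only in modules of 3 or more correlated features).
    Hubs are emitted in stable module-ID order.
    """
    if rule not in ("max_connectivity", "max_mad", "random"):
        raise DimredError(f"unknown hub rule {rule!r}")
    rng = np.random.default_rng(seed) if rule == "random" else None
    out_modules: list[FeatureModule] = []
    selected: list[str] = []
    for mod in modules:
        members = list(mod.member_feature_ids)
        if len(members) == 1:
            hub = members[0]
        elif rule == "random" and len(members) >= randomize_min_size:
            hub = members[int(rng.integers(len(members)))]
        elif rule == "max_mad":
            hub = min(members, key=lambda f: (-mad_values[f], f))
        else:
            sub = corr.loc[members, members].abs().to_numpy()
            np.fill_diagonal(sub, 0.0)
            conn = pd.Series(sub.sum(axis=1), index=members)
            hub = min(members, key=lambda f: (-conn[f], -mad_values[f], f))
        out_modules.append(
            FeatureModule(
                module_id=mod.module_id,
                member_feature_ids=mod.member_feature_ids,
                hub_feature_id=hub,
                corr_threshold=mod.corr_threshold,
                corr_method=mod.corr_method,
            )
        )
        selected.append(hub)
    return ReductionResult(
        selected_feature_ids=selected,
        modules=out_modules,
        mad_values=mad_values,
        parameters={"hub_rule": rule, "seed": seed},
    )


def reduce_features(
    matrix: ProteinMatrix,
    mad_fraction: float = 0.3,
    corr_threshold: float = 0.7,
    corr_method: str = "spearman",
    hub_rule: str = "max_connectivity",
    seed: int | None = None,
    n_rounds: int = 1,
) -> ReductionResult:
    """Full reduction: MAD filter, then ``n_rounds`` of module/hub passes.

    Rounds after the first re-apply module building and hub selection to
    the surviving hub set; a fixed point is reached when no module has two
    or more members, after which further rounds change nothing.
    """
    if n_rounds < 1:
        raise DimredError("n_rounds must be >= 1")
    subset, mad = mad_select(matrix, mad_fraction)
    result = None
    for r in range(n_rounds):
        modules, corr = build_modules(matrix, subset, corr_threshold, corr_method)
        result = select_hubs(
            modules, corr, mad, rule=hub_rule,
            seed=None if seed is None else seed + r,
        )
        if max(m.size for m in modules) < 2:
            break
        subset = result.selected_feature_ids
    result.parameters.update(
        {
            "mad_fraction": mad_fraction,
            "corr_threshold": corr_threshold,
            "corr_method": corr_method,
            "hub_rule": hub_rule,
            "n_rounds": n_rounds,
        }
    )
    return result


def reduction_to_dict(result: ReductionResult) -> dict:
    """JSON-serializable summary of a reduction (modules, hubs, parameters)."""
    return {
        "selected_feature_ids": list(result.selected_feature_ids),
        "modules": [
            {
                "module_id": m.module_id,
                "members": list(m.member_feature_ids),
                "hub": m.hub_feature_id,
            }
            for m in result.modules
        ],
        "parameters": result.parameters,
    }
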