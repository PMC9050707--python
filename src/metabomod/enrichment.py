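"""Pathway over-representation and metabolome-proteome module integration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import EnrichmentInputs, hypergeom_overrep, pearson_test
from .ica import ModuleSet

__all__ = [
    "enrich_module",
    "enrich_modules",
    "CrossOmicsResult",
    "cross_omics_correlation",
    "recurrent_feature_report",
]


def enrich_module(
    module: list[str],
    pathway_map: pd.Series,
    universe: list[str] | None = None,
    p_threshold: float | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway inside one module.

    ``pathway_map`` maps feature id -> pathway label over the universe (by
    default all mapped features). One row per pathway overlapping the module,
    sorted by ascending p; ``ratio`` is overlap/module-size, the bar length
    of the usual enrichment bar plot. Raw p-values are the default
    (``adjust=True`` adds a BH column).
    """
    if universe is None:
        universe = list(pathway_map.index)
    universe_set = set(universe)
    module_set = set(module)
    stray = module_set - universe_set
    if stray:
        raise ValueError(f"module features outside the universe: {sorted(stray)[:10]}")
    pm = pathway_map.loc[[f for f in universe if f in pathway_map.index]]
    N = len(pm)
    m = len(module_set & set(pm.index))
    rows = []
    for pathway, feats in pm.groupby(pm).groups.items():
        k = len(feats)
        x = len(module_set & set(feats))
        if x == 0:
            continue
        p = hypergeom_overrep(
            EnrichmentInputs(overlap_x=x, module_size_m=m, pathway_size_k=k, universe_N=N)
        )
        rows.append(
            {
                "pathway": pathway,
                "overlap_x": x,
                "module_size_m": m,
                "pathway_size_k": k,
                "universe_N": N,
                "ratio": x / m if m else np.nan,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway", "overlap_x", "module_size_m", "pathway_size_k",
            "universe_N", "ratio", "p",
        ],
    ).sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    if adjust and len(out):
        from .stats import bh_fdr

        out["q"] = bh_fdr(out["p"].to_numpy())
    if p_threshold is not None:
        out = out[out["p"] < p_threshold].reset_index(drop=True)
    return out


def enrich_modules(
    modules: ModuleSet,
    annotation: pd.DataFrame,
    level: str = "sub_pathway",
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`enrich_module` for every module; long table keyed by module."""
    if level not in annotation.columns:
        raise ValueError(f"annotation has no level {level!r}")
    pathway_map = annotation[level]
    frames = []
    for name, members in modules:
        t = enrich_module(members, pathway_map, **kwargs)
        t.insert(0, "module", name)
        frames.append(t)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


@dataclass
class CrossOmicsResult:
    """All pairwise module-activity correlations between two omics layers."""

    r: pd.DataFrame  # metabolite modules x protein modules
    p: pd.DataFrame
    pairs: pd.DataFrame  # long table with significance flags
    n_samples: int

    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def cross_omics_correlation(
    met_scores: pd.DataFrame,
    prot_scores: pd.DataFrame,
    p_threshold: float = 0.05,
) -> CrossOmicsResult:
    """Pearson correlation of every metabolite/protein module-score pair.

    Both score tables are restricted to their shared samples (>= 3 required);
    significance uses the raw two-sided p at ``p_threshold``.
    """
    shared = met_scores.index.intersection(prot_scores.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    A = met_scores.loc[shared]
    B = prot_scores.loc[shared]
    r = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    p = r.copy()
    rows = []
    for mc in A.columns:
        for pc in B.columns:
            res = pearson_test(A[mc].to_numpy(), B[pc].to_numpy())
            r.loc[mc, pc] = res.estimate
            p.loc[mc, pc] = res.p_value
            rows.append(
                {
                    "metabolite_module": mc,
                    "protein_module": pc,
                    "r": res.estimate,
                    "p": res.p_value,
                    "significant": res.p_value < p_threshold,
                }
            )
    pairs = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    return CrossOmicsResult(r=r, p=p, pairs=pairs, n_samples=len(shared))


def recurrent_feature_report(module_sets: list[ModuleSet] | ModuleSet) -> pd.DataFrame:
    """How many modules each feature belongs to, across one or more module sets.

    Sorted by count descending (ties by feature id); surfaces hub features
    that recur across modules.
    """
    if isinstance(module_sets, ModuleSet):
        module_sets = [module_sets]
    if not module_sets:
        raise ValueError("need at least one module set")
    counts: dict[str, list[str]] = {}
    for si, ms in enumerate(module_sets):
        for name, members in ms:
            label = name if len(module_sets) == 1 else f"set{si + 1}:{name}"
            for f in members:
                counts.setdefault(f, []).append(label)
    rows = [
        {"feature_id": f, "n_modules": len(mods), "modules": ",".join(mods)}
        for f, mods in counts.items()
    ]
    out = pd.DataFrame(rows, columns=["feature_id", "n_modules", "modules"])
    return out.sort_values(
        ["n_modules", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
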