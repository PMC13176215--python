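"""Over-representation analysis and attribution-weighted pathway scores.

Fisher's exact / hypergeometric upper-tail ORA of a DEG query against GMT
gene-set collections with BH correction across each collection, run overall
and separately per direction, plus a SHAP-weighted pathway score: the mean
attribution importance of a term's genes within the model's feature set.

The default background universe is the measured common-gene set (the
cross-dataset intersection), not the whole genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .deg import benjamini_hochberg
from .synthetic import PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "fisher_ora",
    "enrich_collection",
    "directional_enrichment",
    "shap_weighted_score",
    "ORAResult",
]

MIN_TERM_SIZE = 3
MAX_TERM_SIZE = 500


def read_gmt(path, label: str | None = None) -> PathwayCollection:
    """Read a GMT file (term <tab> description <tab> members...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return PathwayCollection(label=label or Path(path).stem, sets=sets)


def write_gmt(collection: PathwayCollection, path) -> None:
    lines = [
        "\t".join([term, collection.label] + list(members))
        for term, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ORAResult:
    term: str
    k: int  # overlap
    K: int  # term size within universe
    n: int  # query size
    N: int  # universe size
    p_raw: float
    fdr: float | None = None
    overlap: tuple = ()

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds min(term size, query size)")


def fisher_ora(query, term_set, universe) -> ORAResult:
    """One-sided over-representation p-value P(X >= k), hypergeometric.

    Query and term genes outside the universe are intersected away (logged).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= universe:
        logger.warning("query contains %d genes outside the universe; intersecting",
                       len(q - universe))
        q &= universe
    t = set(term_set) & universe
    overlap = sorted(q & t)
    k, K, n, N = len(overlap), len(t), len(q), len(universe)
    # upper tail includes k itself: sf(k-1)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return ORAResult(term="", k=k, K=K, n=n, N=N, p_raw=min(max(p, 0.0), 1.0),
                     overlap=tuple(overlap))


def enrich_collection(
    query,
    collection: PathwayCollection,
    universe,
    fdr_max: float = 0.05,
    min_term_size: int = MIN_TERM_SIZE,
    max_term_size: int = MAX_TERM_SIZE,
) -> pd.DataFrame:
    """ORA of every term in a collection with BH correction across terms."""
    rows = []
    universe_set = set(universe)
    for term, members in collection.sets.items():
        effective = set(members) & universe_set
        if not min_term_size <= len(effective) <= max_term_size:
            continue
        r = fisher_ora(query, members, universe_set)
        r.term = term
        rows.append(r)
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_raw", "fdr", "significant", "overlap"]
        )
    fdrs = benjamini_hochberg([r.p_raw for r in rows])
    table = pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "fdr": fdrs,
            "overlap": ["|".join(r.overlap) for r in rows],
        }
    )
    table["significant"] = table["fdr"] < fdr_max
    return table.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def directional_enrichment(up_set, down_set, collection, universe, fdr_max=0.05):
    """Independent ORA runs for up- and downregulated gene sets."""
    up, down = set(up_set), set(down_set)
    if up & down:
        raise ValueError(f"up/down sets overlap: {sorted(up & down)[:5]}")
    up_res = enrich_collection(up, collection, universe, fdr_max=fdr_max) \
        if up else pd.DataFrame()
    down_res = enrich_collection(down, collection, universe, fdr_max=fdr_max) \
        if down else pd.DataFrame()
    return up_res, down_res


def shap_weighted_score(term_set, importance: pd.DataFrame, feature_set) -> dict:
    """Mean attribution importance of a term's genes within the feature set.

    ``importance`` is a :func:`cdikit.attribution.global_importance` table.
    Terms disjoint from the feature set score 0 with n_contributing_genes 0.
    """
    contributing = sorted(set(term_set) & set(feature_set) & set(importance.index))
    if not contributing:
        return {"shap_score": 0.0, "n_contributing_genes": 0, "genes": ()}
    score = float(importance.loc[contributing, "mean_abs_shap"].mean())
    return {
        "shap_score": score,
        "n_contributing_genes": len(contributing),
        "genes": tuple(contributing),
    }


def score_collection(
    collection: PathwayCollection, importance: pd.DataFrame, feature_set
) -> pd.DataFrame:
    """SHAP-weighted scores for every term of a collection."""
    rows = []
    for term, members in collection.sets.items():
        res = shap_weighted_score(members, importance, feature_set)
        rows.append({"term": term, "shap_score": res["shap_score"],
                     "n_contributing_genes": res["n_contributing_genes"]})
    return (
        pd.DataFrame(rows)
        .sort_values("shap_score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
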