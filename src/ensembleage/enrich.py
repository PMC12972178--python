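"""Hypergeometric enrichment of CpG hit lists in annotation sets.

Annotation content (CpG islands, genomic regions, chromatin states, ...)
is supplied by the user as named CpG id sets; only the test lives here.
Enrichment is one-sided (upper tail): for a universe of N testable CpGs of
which K carry the annotation, and n hits of which k are annotated,

    fold = (k / n) / (K / N)
    p    = P(X >= k),  X ~ Hypergeometric(N, K, n).

Depletion shows up as fold < 1 but is not separately tested.  Signed
enrichment splits EWAS hits by the sign of z before testing and adjusts
p-values per direction with Benjamini-Hochberg across the annotation sets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


def read_annotation_sets(path: str | Path) -> list[AnnotationSet]:
    """Read annotation sets from a two-column CSV (set_name, cpg_id)."""
    groups: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValidationError(f"{path}: expected header set_name,cpg_id")
        for row in reader:
            if len(row) < 2:
                continue
            groups.setdefault(row[0], set()).add(row[1])
    return [AnnotationSet(name, frozenset(m))
            for name, m in sorted(groups.items())]


def enrich(hits: Iterable[str], universe: Iterable[str], ann: AnnotationSet,
           ) -> tuple[int, float, float]:
    """Upper-tail hypergeometric enrichment of ``hits`` in ``ann``.

    Returns (overlap, fold, p).  Annotation members outside the universe
    are dropped (count logged); empty hit lists return (0, nan, 1.0).
    """
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise ValidationError("empty universe")
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    members = ann.members & universe
    dropped = len(ann.members) - len(members)
    if dropped:
        logger.info("annotation %s: %d members outside universe dropped",
                    ann.name, dropped)
    if not hits:
        return 0, float("nan"), 1.0
    N, K, n = len(universe), len(members), len(hits)
    k = len(hits & members)
    fold = (k / n) / (K / N) if K else float("nan")
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
    return k, fold, min(p, 1.0)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out.tolist()


def enrich_signed(ewas_table: pd.DataFrame, ann_sets: Sequence[AnnotationSet],
                  p_thresh: float = 1e-5,
                  universe: Iterable[str] | None = None) -> pd.DataFrame:
    """Directional enrichment of EWAS hits.

    Hits (p < ``p_thresh``) are split by the sign of z; each partition is
    tested against every annotation set and BH-adjusted across sets within
    its direction.  The universe defaults to all testable CpGs of the
    table.  Returns columns set, direction, n_hits, overlap, fold, p, fdr.
    """
    ok = ewas_table[~ewas_table["untestable"].astype(bool)]
    uni = set(universe) if universe is not None else set(ok["cpg_id"])
    sig = ok[ok["p"] < p_thresh]
    partitions = {
        "positive": set(sig.loc[sig["z"] > 0, "cpg_id"]) & uni,
        "negative": set(sig.loc[sig["z"] < 0, "cpg_id"]) & uni,
    }
    rows = []
    for direction, hits in partitions.items():
        for ann in ann_sets:
            k, fold, p = enrich(hits, uni, ann)
            rows.append({"set": ann.name, "direction": direction,
                         "n_hits": len(hits), "overlap": k, "fold": fold,
                         "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["set", "direction", "n_hits", "overlap",
                                    "fold", "p", "fdr"])
    out["fdr"] = float("nan")
    for direction in partitions:
        mask = out["direction"] == direction
        out.loc[mask, "fdr"] = bh_adjust(out.loc[mask, "p"].tolist())
    return out
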