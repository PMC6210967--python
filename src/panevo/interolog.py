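"""Interolog transfer of host-microbe protein-protein interactions.

A microbe protein M and a host protein H are predicted to interact when M
is homologous to template protein T1, H to T2, and (T1, T2) is a known
(template) interaction whose detection method is not a co-complex method.
Homology hits are filtered on e-value, percent identity, and query/template
coverage; retained edges additionally satisfy *joint* thresholds defined
worst-of-pair: joint e-value = max of the two mapped hit e-values, joint
identity = min of the two identities.  (The worst-of-pair convention is
this package's explicit definition of the joint scores; it is the
conservative reading and it changes edge counts, so it is fixed and
documented rather than left implicit.)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyFilter",
    "filter_hits",
    "predict_interologs",
    "summarize_network",
]

HIT_COLUMNS = ["query_id", "template_id", "evalue", "pct_identity", "query_coverage_pct", "template_coverage_pct"]
TEMPLATE_COLUMNS = ["template_a", "template_b", "detection_method"]

DEFAULT_EXCLUDED_METHODS = frozenset({"tandem affinity purification"})


@dataclass(frozen=True)
class HomologyFilter:
    """Homology acceptance thresholds (the interolog-server defaults)."""

    evalue_max: float = 1e-10
    identity_min: float = 30.0
    query_cov_min: float = 60.0
    template_cov_min: float = 90.0


def filter_hits(hits: pd.DataFrame, thresholds: HomologyFilter | None = None) -> tuple[pd.DataFrame, dict]:
    """Apply the four homology thresholds to a hit table.

    A hit survives iff evalue <= evalue_max, identity >= identity_min,
    query coverage >= query_cov_min and template coverage >=
    template_cov_min.  Returns the surviving rows and a tally of rejection
    reasons (a hit failing several thresholds counts under each).
    """
    if thresholds is None:
        thresholds = HomologyFilter()
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    fail_e = hits["evalue"] > thresholds.evalue_max
    fail_i = hits["pct_identity"] < thresholds.identity_min
    fail_q = hits["query_coverage_pct"] < thresholds.query_cov_min
    fail_t = hits["template_coverage_pct"] < thresholds.template_cov_min
    rejected = {
        "evalue": int(fail_e.sum()),
        "identity": int(fail_i.sum()),
        "query_coverage": int(fail_q.sum()),
        "template_coverage": int(fail_t.sum()),
    }
    keep = ~(fail_e | fail_i | fail_q | fail_t)
    return hits[keep].reset_index(drop=True), rejected


def _method_excluded(method: str, excluded: frozenset[str] | set[str]) -> bool:
    m = str(method).lower()
    return any(pat.lower() in m for pat in excluded)


def predict_interologs(
    microbe_hits: pd.DataFrame,
    host_hits: pd.DataFrame,
    template_edges: pd.DataFrame,
    thresholds: HomologyFilter | None = None,
    exclude_methods: set[str] | frozenset[str] = DEFAULT_EXCLUDED_METHODS,
) -> pd.DataFrame:
    """Transfer template interactions to (microbe, host) protein pairs.

    For every template edge (t1, t2) whose detection method does not match
    an excluded co-complex method (case-insensitive substring), every
    microbe protein mapped to t1 crossed with every host protein mapped to
    t2 — and the symmetric assignment — yields a candidate edge.  Joint
    metrics are computed worst-of-pair and candidates failing the joint
    thresholds (evalue_max / identity_min again) are dropped.  Edges are
    deduplicated by (microbe, host) with supporting template pairs merged;
    the best (lowest) joint e-value and best (highest) joint identity over
    supports are reported.
    """
    if thresholds is None:
        thresholds = HomologyFilter()
    missing = [c for c in TEMPLATE_COLUMNS if c not in template_edges.columns]
    if missing:
        raise ValueError(f"template edge table missing columns {missing}")
    if len(template_edges) == 0:
        logger.warning("empty template interaction set: no predictions possible")
        return _empty_predictions()

    microbe_hits, _ = filter_hits(microbe_hits, thresholds)
    host_hits, _ = filter_hits(host_hits, thresholds)

    templates = template_edges[
        ~template_edges["detection_method"].map(lambda m: _method_excluded(m, exclude_methods))
    ]

    by_template_m: dict[str, list] = {}
    for row in microbe_hits.itertuples(index=False):
        by_template_m.setdefault(row.template_id, []).append(row)
    by_template_h: dict[str, list] = {}
    for row in host_hits.itertuples(index=False):
        by_template_h.setdefault(row.template_id, []).append(row)

    merged: dict[tuple[str, str], dict] = {}
    for trow in templates.itertuples(index=False):
        t1, t2 = trow.template_a, trow.template_b
        for ta, tb in ((t1, t2), (t2, t1)) if t1 != t2 else ((t1, t2),):
            for mh in by_template_m.get(ta, ()):
                for hh in by_template_h.get(tb, ()):
                    joint_e = max(mh.evalue, hh.evalue)
                    joint_i = min(mh.pct_identity, hh.pct_identity)
                    if joint_e > thresholds.evalue_max or joint_i < thresholds.identity_min:
                        continue
                    key = (mh.query_id, hh.query_id)
                    support = (ta, tb, trow.detection_method)
                    entry = merged.setdefault(
                        key,
                        {"supports": [], "joint_evalue": joint_e, "joint_identity": joint_i},
                    )
                    if support not in entry["supports"]:
                        entry["supports"].append(support)
                    entry["joint_evalue"] = min(entry["joint_evalue"], joint_e)
                    entry["joint_identity"] = max(entry["joint_identity"], joint_i)

    if not merged:
        return _empty_predictions()
    rows = [
        {
            "microbe_protein": m,
            "host_protein": h,
            "joint_evalue": entry["joint_evalue"],
            "joint_identity": entry["joint_identity"],
            "n_supports": len(entry["supports"]),
            "supporting_templates": ";".join(f"{a}|{b}|{meth}" for a, b, meth in entry["supports"]),
        }
        for (m, h), entry in sorted(merged.items())
    ]
    return pd.DataFrame(rows)


def _empty_predictions() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "microbe_protein",
            "host_protein",
            "joint_evalue",
            "joint_identity",
            "n_supports",
            "supporting_templates",
        ]
    )


def summarize_network(
    edges: pd.DataFrame,
    immunity_genes: set[str] | None = None,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Counts and composition of a predicted interaction network.

    Reports distinct microbe/host protein and edge counts, the
    immunity-restricted subnetwork (host proteins in ``immunity_genes``),
    per-microbe-protein degrees, and — when an annotation table
    (host_protein, category) is given — the percentage composition over
    annotated host proteins (sums to 100).
    """
    summary: dict = {
        "n_edges": int(len(edges)),
        "n_microbe_proteins": int(edges["microbe_protein"].nunique()) if len(edges) else 0,
        "n_host_proteins": int(edges["host_protein"].nunique()) if len(edges) else 0,
    }
    if len(edges):
        degrees = edges.groupby("microbe_protein")["host_protein"].nunique().sort_values(ascending=False)
        summary["microbe_degrees"] = degrees.to_dict()
    else:
        summary["microbe_degrees"] = {}

    if immunity_genes is not None:
        sub = edges[edges["host_protein"].isin(immunity_genes)] if len(edges) else edges
        summary["immunity"] = {
            "n_edges": int(len(sub)),
            "n_microbe_proteins": int(sub["microbe_protein"].nunique()) if len(sub) else 0,
            "n_host_proteins": int(sub["host_protein"].nunique()) if len(sub) else 0,
        }

    if annotations is not None and len(edges):
        ann = annotations.set_index("host_protein")["category"]
        hosts = edges["host_protein"].drop_duplicates()
        cats = hosts.map(ann).dropna()
        if len(cats):
            pct = (cats.value_counts() / len(cats) * 100.0).round(6)
            summary["host_category_pct"] = pct.to_dict()
        else:
            summary["host_category_pct"] = {}
    return summary
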