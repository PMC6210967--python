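"""Feature-abundance statistics and conserved-peptide scanning.

Correlates per-genome functional-category (COG class) and mobilome feature
abundances with genome size by Spearman rank correlation, tests group
differences with Kruskal-Wallis, and scans proteomes for short conserved
peptides allowing a bounded number of mismatches.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "COG_CLASSES",
    "SPEARMAN_EXACT_MAX_N",
    "SpearmanResult",
    "cog_abundance_matrix",
    "spearman",
    "correlate_with_genome_size",
    "kruskal_wallis",
    "PeptideHit",
    "PeptideScanResult",
    "peptide_scan",
]

#: the lettered COG functional classes
COG_CLASSES = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

#: columns produced but excluded from genome-size correlations: genes of
#: General Function Prediction Only (R) and Function Unknown (S) carry no
#: functional signal, and multi-class genes are tallied once under MC
EXCLUDED_FROM_CORRELATION = ("R", "S", "MC")

SPEARMAN_EXACT_MAX_N = 9


def cog_abundance_matrix(assignments: pd.DataFrame, genome_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-genome COG-class count matrix.

    ``assignments`` needs columns gene_id, genome_id, classes (one or more
    class letters, e.g. ``"G"`` or ``"GK"``; separators ``,;/`` and spaces
    tolerated).  A gene with more than one class is counted once under
    ``MC`` (multiple classes) only.  Unknown class letters raise, naming
    the offending row.
    """
    required = {"gene_id", "genome_id", "classes"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignment table must have columns {sorted(required)}")
    rows: dict[str, dict[str, int]] = {}
    for i, row in assignments.iterrows():
        letters = [c for c in str(row["classes"]).upper() if c not in ",;/ "]
        bad = [c for c in letters if c not in COG_CLASSES]
        if bad or not letters:
            raise ValueError(
                f"row {i} (gene {row['gene_id']!r}): unknown COG class letter(s) {bad or '<none>'}"
            )
        key = "MC" if len(set(letters)) > 1 else letters[0]
        rows.setdefault(row["genome_id"], {})
        rows[row["genome_id"]][key] = rows[row["genome_id"]].get(key, 0) + 1
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if genome_ids is not None:
        table = table.reindex(genome_ids, fill_value=0)
    table.index.name = "genome_id"
    return table.sort_index(axis=1)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True
    method: str = "t-approximation"


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t-approximation with n-2 degrees of freedom for
    n >= 10 and exact full permutation for smaller samples.  A constant
    vector makes rho undefined (flagged, not an exception).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), n, defined=False, method="undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if len(set(rx)) == n and len(set(ry)) == n:
        # tie-free: the textbook closed form is exact (no float drift)
        d2 = float(np.sum((rx - ry) ** 2))
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > SPEARMAN_EXACT_MAX_N:
        res = sps.spearmanr(x, y)
        return SpearmanResult(rho, float(res.pvalue), n, method="t-approximation")
    # exact permutation null: |rho| is monotone in |centered rank dot product|
    # because every permutation of the same rank multiset has the same variance
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    observed = abs(float(np.dot(rxc, ry - ry.mean())))
    null = np.abs((perms - ry.mean()) @ rxc)
    p = float(np.mean(null >= observed - 1e-9))
    return SpearmanResult(rho, p, n, method="exact-permutation")


def correlate_with_genome_size(
    table: pd.DataFrame, alpha: float = 0.001, exclude: tuple[str, ...] = EXCLUDED_FROM_CORRELATION
) -> pd.DataFrame:
    """Spearman correlation of every feature column against genome size.

    Columns listed in ``exclude`` (by default R, S, and MC) are produced
    upstream but omitted here.  Returns a report sorted by rho with a
    significance flag at ``alpha`` (default 0.001).
    """
    if "genome_size_bp" not in table.columns:
        raise ValueError("feature table must contain genome_size_bp")
    size = table["genome_size_bp"].to_numpy(dtype=float)
    rows = []
    for col in table.columns:
        if col in ("genome_id", "genome_size_bp") or col in exclude:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        mask = vals.notna()
        if mask.sum() < 4:
            continue
        res = spearman(size[mask.to_numpy()], vals[mask].to_numpy())
        rows.append(
            {
                "feature": col,
                "spearman_rho": res.rho,
                "p_value": res.p_value,
                "significant": bool(res.defined and res.p_value < alpha),
                "n": res.n,
            }
        )
    report = pd.DataFrame(rows)
    return report.sort_values("spearman_rho", ascending=False).reset_index(drop=True)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class PeptideHit:
    gene_id: str
    position: int  # 0-based offset in the protein
    mismatches: tuple[tuple[int, str, str], ...]  # (peptide position, expected, found)


@dataclass
class PeptideScanResult:
    peptide: str
    max_mismatch: int
    exact_hits: list[PeptideHit] = field(default_factory=list)
    variant_hits: list[PeptideHit] = field(default_factory=list)

    @property
    def n_exact(self) -> int:
        return len(self.exact_hits)

    @property
    def n_variant(self) -> int:
        return len(self.variant_hits)


def peptide_scan(
    proteome: list[tuple[str, str]], peptide: str = "FAIVDEVDSILIDEAR", max_mismatch: int = 1
) -> PeptideScanResult:
    """Sliding-window scan of a proteome for a conserved peptide.

    Exact hits are substring matches; variant hits differ at 1 to
    ``max_mismatch`` positions.  The default query is the SecA-encrypted
    immunomodulatory peptide whose single-residue variant (F1Y) is the
    common form across gut bifidobacteria.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    peptide = peptide.upper()
    k = len(peptide)
    result = PeptideScanResult(peptide=peptide, max_mismatch=max_mismatch)
    for gene_id, seq in proteome:
        seq = seq.upper()
        for off in range(len(seq) - k + 1):
            window = seq[off : off + k]
            mism = tuple(
                (i, peptide[i], window[i]) for i in range(k) if window[i] != peptide[i]
            )
            if not mism:
                result.exact_hits.append(PeptideHit(gene_id, off, ()))
            elif len(mism) <= max_mismatch:
                result.variant_hits.append(PeptideHit(gene_id, off, mism))
    return result
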