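"""Selection-pressure analyses: codon-usage relative entropy and NG86 Ka/Ks.

Two complementary views of selection on a gene set:

* **Relative entropy** of codon usage, the Kullback-Leibler divergence (in
  bits) between observed codon frequencies and a null expectation, computed
  per genome for a designated gene subset (typically the core genes) and
  for the whole chromosome, then compared across genomes with Welch's
  unequal-variance t-test.  Higher divergence from the null marks stronger
  codon-level selection.

* **Ka/Ks (omega)** by the Nei-Gojobori counting method on codon
  alignments: per-codon synonymous/nonsynonymous site counts, per-pair
  difference counts averaged over all minimal mutational pathways, and the
  Jukes-Cantor multiple-hit correction; omega < 1 indicates purifying
  selection, omega > 1 positive (Darwinian) selection.

Convention choices that the counting literature leaves open are pinned here
and tested: mutations to stop codons count as nonsynonymous in site
counting (preserving s + n = 3 per codon); pathways through stop codons
are excluded from difference counting unless every pathway is blocked, in
which case all pathways are used; omega is *undefined* (not 0 or infinity)
when Ks = 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from ._genetics import (
    CODON_TO_AA,
    SENSE_CODONS,
    SENSE_INDEX,
    SYNONYMOUS_FAMILIES,
    single_mutants,
    translate_cds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodonCounts",
    "EntropyResult",
    "KaKsRecord",
    "observed_codon_frequencies",
    "expected_codon_frequencies",
    "relative_entropy",
    "compare_core_vs_chromosome",
    "codon_align",
    "ng_site_counts",
    "ng_differences",
    "ng_kaks",
    "family_omega",
]

_UNAMBIGUOUS = frozenset("ACGT")


# ---------------------------------------------------------------------------
# codon-usage relative entropy


@dataclass
class CodonCounts:
    """Counts over the 61 sense codons for a labelled gene set."""

    counts: np.ndarray
    label: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _iter_cds(cds_set):
    for item in cds_set:
        if isinstance(item, str):
            yield "<unnamed>", item
        else:
            yield item


def observed_codon_frequencies(cds_set, label: str = "") -> CodonCounts:
    """Tally sense codons over a set of CDS.

    Accepts plain sequences or (gene_id, sequence) pairs.  Codons containing
    ambiguous bases and stop codons are skipped; a CDS whose length is not a
    multiple of 3 raises, naming the gene.
    """
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for gene_id, cds in _iter_cds(cds_set):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"gene {gene_id!r}: CDS length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            idx = SENSE_INDEX.get(cds[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("no usable (sense, unambiguous) codons in the input")
    return CodonCounts(counts=counts, label=label)


def expected_codon_frequencies(
    observed: CodonCounts, null_model: str = "positional_nucleotide"
) -> np.ndarray:
    """Null-model codon frequency vector over the 61 sense codons.

    ``positional_nucleotide`` (default): the expectation for codon xyz is
    the product of position-specific nucleotide frequencies f1(x) f2(y)
    f3(z) estimated from the same counts, renormalized over sense codons —
    the usage expected if the three codon positions were independent.
    ``uniform_synonymous``: each codon's expectation is its amino acid's
    observed frequency split equally over the synonymous family.  Both sum
    to 1.  Zero expectations where the observed count is positive trigger a
    logged pseudocount fallback.
    """
    counts = observed.counts
    if counts.sum() == 0:
        raise ValueError("empty codon counts")
    if null_model == "positional_nucleotide":
        pos_freq = np.zeros((3, 4))
        nt_index = {nt: i for i, nt in enumerate("ACGT")}
        for codon, c in zip(SENSE_CODONS, counts):
            for pos in range(3):
                pos_freq[pos, nt_index[codon[pos]]] += c
        pos_freq /= pos_freq.sum(axis=1, keepdims=True)
        expected = np.array(
            [
                pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
                for c in SENSE_CODONS
            ]
        )
    elif null_model == "uniform_synonymous":
        freqs = counts / counts.sum()
        expected = np.zeros_like(freqs)
        for codons in SYNONYMOUS_FAMILIES.values():
            idx = [SENSE_INDEX[c] for c in codons]
            expected[idx] = freqs[idx].sum() / len(idx)
    else:
        raise ValueError(f"unknown null model {null_model!r}")

    if np.any((expected == 0) & (counts > 0)):
        logger.warning("zero expected frequency with positive observed count; applying pseudocount")
        expected = expected + 1e-9
    return expected / expected.sum()


def relative_entropy(observed: CodonCounts, expected: np.ndarray) -> float:
    """Kullback-Leibler divergence D(observed || expected) in bits.

    Zero-observed codons contribute nothing; a positive observed frequency
    over a zero expectation raises.
    """
    p = observed.frequencies
    q = np.asarray(expected, dtype=float)
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("expected frequencies must be positive wherever observed > 0")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


#: free parameters fitted by each null model (positional: 3 positions x 3
#: free nucleotide frequencies; uniform_synonymous: 19 free amino-acid
#: frequencies), used by the finite-sample bias correction
_NULL_MODEL_PARAMS = {"positional_nucleotide": 9, "uniform_synonymous": 19}


def estimate_relative_entropy(
    observed: CodonCounts, null_model: str = "positional_nucleotide", bias_correction: bool = True
) -> float:
    """Bias-corrected relative-entropy estimate (bits) for a gene set.

    The plug-in Kullback-Leibler estimate carries a positive finite-sample
    bias of about (k - 1 - d) / (2 N ln 2) bits (k = 61 sense codons, d =
    null-model parameters, N = codon count), so smaller gene sets look
    spuriously more divergent.  Comparing a core set against a whole
    chromosome without the correction inflates the difference purely
    through set size; with it, equal-bias sets of unequal size score
    equally in expectation.  The correction is a deterministic offset and
    can push near-null estimates slightly below zero.
    """
    dkl = relative_entropy(observed, expected_codon_frequencies(observed, null_model))
    if not bias_correction:
        return dkl
    d = _NULL_MODEL_PARAMS[null_model]
    n = observed.total
    return dkl - (len(SENSE_CODONS) - 1 - d) / (2.0 * n * math.log(2.0))


@dataclass
class EntropyResult:
    """Per-genome relative entropies plus the Welch comparison."""

    dkl_core: pd.Series
    dkl_chromosome: pd.Series
    welch_t: float
    welch_df: float
    p_two_sided: float
    p_one_sided_core_greater: float

    def to_dict(self) -> dict:
        return {
            "welch_t": self.welch_t,
            "welch_df": self.welch_df,
            "p_two_sided": self.p_two_sided,
            "p_one_sided_core_greater": self.p_one_sided_core_greater,
            "mean_dkl_core": float(self.dkl_core.mean()),
            "mean_dkl_chromosome": float(self.dkl_chromosome.mean()),
        }


def compare_core_vs_chromosome(core_dkls, chrom_dkls) -> EntropyResult:
    """Welch's unequal-variance t-test between the two per-genome groups."""
    core = pd.Series(core_dkls, dtype=float)
    chrom = pd.Series(chrom_dkls, dtype=float)
    if len(core) < 2 or len(chrom) < 2:
        raise ValueError("both groups need >= 2 values")
    if core.var(ddof=1) == 0 and chrom.var(ddof=1) == 0:
        if core.mean() == chrom.mean():
            return EntropyResult(core, chrom, 0.0, float(len(core) + len(chrom) - 2), 1.0, 0.5)
        t, df = math.inf * np.sign(core.mean() - chrom.mean()), float(len(core) + len(chrom) - 2)
        return EntropyResult(core, chrom, t, df, 0.0, 0.0 if t > 0 else 1.0)
    res = stats.ttest_ind(core, chrom, equal_var=False)
    one_sided = stats.ttest_ind(core, chrom, equal_var=False, alternative="greater")
    return EntropyResult(
        dkl_core=core,
        dkl_chromosome=chrom,
        welch_t=float(res.statistic),
        welch_df=float(res.df),
        p_two_sided=float(res.pvalue),
        p_one_sided_core_greater=float(one_sided.pvalue),
    )


# ---------------------------------------------------------------------------
# codon alignment


def _align_proteins_center_star(proteins: list[str]) -> list[str]:
    """Progressive (center-star) global protein alignment.

    The longest sequence anchors the alignment; every other sequence is
    globally aligned to it with BLOSUM62/affine-gap scoring and the
    pairwise gap patterns are merged over the anchor's coordinate system.
    """
    from Bio.Align import PairwiseAligner

    center_i = max(range(len(proteins)), key=lambda i: (len(proteins[i]), -i))
    center = proteins[center_i]
    aligner = PairwiseAligner(scoring="blastp")
    aligner.mode = "global"

    # per-sequence: insertions before each center residue (slot 0..len(center))
    per_seq: list[tuple[list[str], list[str]]] = []
    for seq in proteins:
        if seq == center:
            ins = [""] * (len(center) + 1)
            cols = list(seq)
            per_seq.append((ins, cols))
            continue
        aln = aligner.align(center, seq)[0]
        ac, as_ = str(aln[0]), str(aln[1])
        ins = [""] * (len(center) + 1)
        cols = []
        ci = 0
        for x, y in zip(ac, as_):
            if x == "-":
                ins[ci] += y
            else:
                cols.append(y)
                ci += 1
        per_seq.append((ins, cols))

    max_ins = [max(len(per_seq[s][0][i]) for s in range(len(proteins))) for i in range(len(center) + 1)]
    aligned = []
    for ins, cols in per_seq:
        parts = []
        for i in range(len(center)):
            parts.append(ins[i].ljust(max_ins[i], "-"))
            parts.append(cols[i])
        parts.append(ins[len(center)].ljust(max_ins[len(center)], "-"))
        aligned.append("".join(parts))
    return aligned


def codon_align(family_cds: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Codon-aware alignment of a gene family's CDS.

    Proteins are aligned globally and the alignment is back-translated to
    codons (one '---' per protein gap).  Sequences with internal stop
    codons are dropped with a log entry.  Downstream NG counting excludes
    any column with a gap.
    """
    usable: list[tuple[str, str, str]] = []
    for gene_id, cds in family_cds:
        try:
            prot = translate_cds(cds)
        except ValueError as exc:
            logger.warning("dropping %s from codon alignment: %s", gene_id, exc)
            continue
        usable.append((gene_id, cds.upper(), prot))
    if not usable:
        raise ValueError("no translatable CDS in family")

    proteins = [p for _, _, p in usable]
    aligned_prots = proteins if len(usable) == 1 else _align_proteins_center_star(proteins)

    out = []
    for (gene_id, cds, _), aligned in zip(usable, aligned_prots):
        codons = []
        ci = 0
        for aa in aligned:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * ci : 3 * ci + 3])
                ci += 1
        out.append((gene_id, "".join(codons)))
    return out


def drop_gapped_columns(alignment: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Remove every codon column in which any sequence has a gap."""
    if not alignment:
        return alignment
    seqs = [s for _, s in alignment]
    length = len(seqs[0]) // 3
    keep = [
        i
        for i in range(length)
        if all(s[3 * i : 3 * i + 3] != "---" for s in seqs)
    ]
    return [(gid, "".join(s[3 * i : 3 * i + 3] for i in keep)) for (gid, _), s in zip(alignment, seqs)]


# ---------------------------------------------------------------------------
# Nei-Gojobori


@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for a sense codon.

    Each of the nine single-nucleotide changes is classified under the
    standard code; changes to stop codons count as nonsynonymous, so
    s + n = 3 exactly.
    """
    codon = codon.upper()
    aa = CODON_TO_AA.get(codon)
    if aa is None or set(codon) - _UNAMBIGUOUS:
        raise ValueError(f"{codon!r} is not an unambiguous sense codon")
    s = sum(1.0 / 3.0 for _, _, mut in single_mutants(codon) if CODON_TO_AA.get(mut) == aa)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between codons.

    All minimal mutational pathways (orderings of the differing positions)
    are enumerated; pathways whose intermediate codons are stops are
    excluded, falling back to all pathways when every one is blocked.  Step
    classification: synonymous iff the amino acid is unchanged (steps
    touching a stop codon count as nonsynonymous).  s_d + n_d equals the
    number of differing positions.
    """
    a, b = a.upper(), b.upper()
    if a not in CODON_TO_AA or b not in CODON_TO_AA:
        raise ValueError("ng_differences requires sense codons")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order):
        syn = nonsyn = 0
        blocked = False
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = CODON_TO_AA.get(cur), CODON_TO_AA.get(nxt)
            if aa_nxt is None and nxt != b:
                blocked = True
            if aa_cur is not None and aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn, blocked

    pathways = [walk(order) for order in itertools.permutations(diff)]
    open_paths = [p for p in pathways if not p[2]]
    used = open_paths if open_paths else pathways
    s_d = sum(p[0] for p in used) / len(used)
    n_d = sum(p[1] for p in used) / len(used)
    return s_d, n_d


@dataclass
class KaKsRecord:
    """NG86 counts and corrected rates for a pair (or family aggregate)."""

    S: float
    N: float
    s_d: float
    n_d: float
    p_s: float
    p_n: float
    Ka: float
    Ks: float
    omega: float  # nan when undefined
    omega_defined: bool
    saturated: bool
    n_codons: int = 0
    excluded_pairs: int = 0
    valid: bool = True

    def as_row(self) -> dict:
        return {
            "S": self.S,
            "N": self.N,
            "s_d": self.s_d,
            "n_d": self.n_d,
            "p_s": self.p_s,
            "p_n": self.p_n,
            "Ka": self.Ka,
            "Ks": self.Ks,
            "omega": self.omega,
            "omega_defined": self.omega_defined,
            "saturated": self.saturated,
            "n_codons": self.n_codons,
            "excluded_pairs": self.excluded_pairs,
        }


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng_kaks(seq_a: str, seq_b: str) -> KaKsRecord:
    """NG86 Ka/Ks for a pair of aligned, gap-free codon sequences.

    Site counts are averaged over the two sequences; differences are summed
    per codon column; Jukes-Cantor corrects p_s and p_n; omega is flagged
    undefined when Ks = 0 and the record flagged saturated when either
    proportion reaches 3/4.  Columns containing gaps, ambiguous bases, or
    stop codons are skipped.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    S = N = s_d = n_d = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue
        sa, na = ng_site_counts(ca)
        sb, nb = ng_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = ng_differences(ca, cb)
        s_d += ds
        n_d += dn
        used += 1
    if used == 0:
        return KaKsRecord(0, 0, 0, 0, 0, 0, 0, 0, float("nan"), False, False, 0, valid=False)
    p_s = s_d / S if S > 0 else 0.0
    p_n = n_d / N if N > 0 else 0.0
    Ks = _jukes_cantor(p_s)
    Ka = _jukes_cantor(p_n)
    saturated = math.isnan(Ks) or math.isnan(Ka)
    omega_defined = (not saturated) and Ks > 0
    omega = Ka / Ks if omega_defined else float("nan")
    return KaKsRecord(
        S=S,
        N=N,
        s_d=s_d,
        n_d=n_d,
        p_s=p_s,
        p_n=p_n,
        Ka=Ka,
        Ks=Ks,
        omega=omega,
        omega_defined=omega_defined,
        saturated=saturated,
        n_codons=used,
    )


def family_omega(alignment: list[tuple[str, str]]) -> KaKsRecord:
    """Aggregate NG86 record for a family's codon alignment.

    Gap-containing columns are removed globally, all pairwise records are
    computed, and the family Ka and Ks are the means over defined,
    unsaturated pairs; family omega is their ratio.  Excluded pairs are
    counted; a family with no valid pair is returned flagged rather than
    dropped.
    """
    if len(alignment) < 2:
        raise ValueError("family_omega requires >= 2 sequences")
    clean = drop_gapped_columns(alignment)
    seqs = [s for _, s in clean]
    records = [ng_kaks(a, b) for a, b in itertools.combinations(seqs, 2)]
    good = [r for r in records if r.valid and not r.saturated and not math.isnan(r.Ks)]
    excluded = len(records) - len(good)
    if not good:
        return KaKsRecord(
            0, 0, 0, 0, 0, 0, float("nan"), float("nan"), float("nan"), False, False, 0,
            excluded_pairs=excluded, valid=False,
        )
    Ka = float(np.mean([r.Ka for r in good]))
    Ks = float(np.mean([r.Ks for r in good]))
    omega_defined = Ks > 0
    return KaKsRecord(
        S=float(np.mean([r.S for r in good])),
        N=float(np.mean([r.N for r in good])),
        s_d=float(np.mean([r.s_d for r in good])),
        n_d=float(np.mean([r.n_d for r in good])),
        p_s=float(np.mean([r.p_s for r in good])),
        p_n=float(np.mean([r.p_n for r in good])),
        Ka=Ka,
        Ks=Ks,
        omega=Ka / Ks if omega_defined else float("nan"),
        omega_defined=omega_defined,
        saturated=False,
        n_codons=good[0].n_codons,
        excluded_pairs=excluded,
    )
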