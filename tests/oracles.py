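"""Independent reference implementations used only as test oracles.

Everything here is written from first principles (including its own copy of
the standard genetic code) so that agreement with the package is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import math

# standard genetic code, transl_table=1, codons enumerated with bases in
# the order T, C, A, G at each position (the classic NCBI layout)
_NCBI_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_NCBI_BASE_ORDER = "TCAG"

GENETIC_CODE: dict[str, str] = {}
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_NCBI_BASE_ORDER, repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _NCBI_AAS[_i]

SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def site_counts(codon: str) -> tuple[float, float]:
    """9-mutation enumeration of synonymous/nonsynonymous site counts."""
    aa = GENETIC_CODE[codon]
    assert aa != "*"
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def pathway_differences(a: str, b: str) -> tuple[float, float]:
    """Exhaustive minimal-pathway enumeration of (s_d, n_d).

    Pathways through stop codons are excluded; if every pathway is blocked
    all are used.  A step is synonymous iff it conserves the amino acid
    (steps into or out of a stop are nonsynonymous).
    """
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    open_paths = []
    for order in itertools.permutations(positions):
        current = a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            mutated = current[:pos] + b[pos] + current[pos + 1 :]
            if GENETIC_CODE[mutated] == "*" and mutated != b:
                through_stop = True
            if GENETIC_CODE[current] != "*" and GENETIC_CODE[current] == GENETIC_CODE[mutated]:
                syn += 1
            else:
                nonsyn += 1
            current = mutated
        all_paths.append((syn, nonsyn))
        if not through_stop:
            open_paths.append((syn, nonsyn))
    used = open_paths or all_paths
    return (
        sum(p[0] for p in used) / len(used),
        sum(p[1] for p in used) / len(used),
    )


def kaks_pair(seq_a: str, seq_b: str) -> dict:
    """Column-by-column NG computation with Jukes-Cantor correction."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if GENETIC_CODE.get(ca, "*") == "*" or GENETIC_CODE.get(cb, "*") == "*":
            continue
        sa, na = site_counts(ca)
        sb, nb = site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = pathway_differences(ca, cb)
        sd += ds
        nd += dn

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0

    ps, pn = sd / S, nd / N
    return {"S": S, "N": N, "s_d": sd, "n_d": nd, "p_s": ps, "p_n": pn, "Ks": jc(ps), "Ka": jc(pn)}


def naive_greedy_cluster(records, threshold, identity_fn):
    """Straight-line restatement of the greedy clustering rule.

    Sort longest-first (ties by gene id), join the first centroid at or
    above the threshold, else found a new cluster.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.gene_id))
    centroids = []  # list of (record, member gene ids)
    for rec in ordered:
        for cent, members in centroids:
            if identity_fn(rec, cent) >= threshold:
                members.append(rec.gene_id)
                break
        else:
            centroids.append((rec, [rec.gene_id]))
    return [frozenset(members) for _, members in centroids]


def brute_rarefaction(presence_rows: dict[str, set[str]], order: list[str]):
    """Set-algebra recomputation of pan/core curves along one genome order.

    ``presence_rows`` maps genome id to its set of family ids.
    """
    pan_curve, core_curve = [], []
    pan: set[str] = set()
    core: set[str] | None = None
    for genome in order:
        fams = presence_rows[genome]
        pan |= fams
        core = set(fams) if core is None else core & fams
        pan_curve.append(len(pan))
        core_curve.append(len(core))
    return pan_curve, core_curve


def naive_peptide_hits(protein: str, peptide: str, max_mismatch: int):
    """Windowed comparison, counting exact and <=k-mismatch occurrences."""
    exact, variant = [], []
    k = len(peptide)
    for off in range(len(protein) - k + 1):
        mm = sum(1 for i in range(k) if protein[off + i] != peptide[i])
        if mm == 0:
            exact.append(off)
        elif mm <= max_mismatch:
            variant.append(off)
    return exact, variant


def brute_interologs(microbe_hits, host_hits, template_edges, evalue_max, identity_min,
                     query_cov_min, template_cov_min, excluded_methods):
    """Exhaustive cross-join enumeration of interolog candidates.

    Returns the set of (microbe, host) pairs surviving all filters.
    """

    def hit_ok(h):
        return (
            h["evalue"] <= evalue_max
            and h["pct_identity"] >= identity_min
            and h["query_coverage_pct"] >= query_cov_min
            and h["template_coverage_pct"] >= template_cov_min
        )

    edges = set()
    for edge in template_edges:
        if any(x.lower() in str(edge["detection_method"]).lower() for x in excluded_methods):
            continue
        for t_m, t_h in {(edge["template_a"], edge["template_b"]), (edge["template_b"], edge["template_a"])}:
            for mh in microbe_hits:
                if mh["template_id"] != t_m or not hit_ok(mh):
                    continue
                for hh in host_hits:
                    if hh["template_id"] != t_h or not hit_ok(hh):
                        continue
                    if max(mh["evalue"], hh["evalue"]) > evalue_max:
                        continue
                    if min(mh["pct_identity"], hh["pct_identity"]) < identity_min:
                        continue
                    edges.add((mh["query_id"], hh["query_id"]))
    return edges
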