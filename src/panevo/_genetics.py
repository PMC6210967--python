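"""Standard genetic code tables shared across the package.

All codon-level machinery (the simulator, Nei-Gojobori counting, codon-usage
tallies) works on the 61 sense codons of the standard (NCBI table 1) code.
Stop codons are never counted as sites of codon usage; mutations *to* a stop
are handled explicitly by the callers (rejected by the simulator, counted as
nonsynonymous in site counting).
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"

_table = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)) if c not in STOP_CODONS)
)

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def single_mutants(codon: str):
    """Yield (position, new_nucleotide, mutated_codon) for all 9 single changes."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, nt, codon[:pos] + nt + codon[pos + 1 :]


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3, sense codons only) to protein.

    A trailing stop codon is tolerated and dropped; internal stops raise.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            if codon in STOP_CODONS and i == n_codons - 1:
                break
            raise ValueError(f"non-sense codon {codon!r} at codon {i}")
        aas.append(aa)
    return "".join(aas)
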