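"""Synthetic pan-genome datasets with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, with every quantity of interest planted and recoverable:

* a gene-family pool with core / accessory / unique structure whose
  rarefaction curve follows a tunable Heaps power law (open mode) or
  saturates on a finite pool (closed mode);
* codon-level divergence between genome copies of a family with a
  controlled nonsynonymous/synonymous rate ratio (omega) and synonymous
  divergence (Ks);
* genome-set-level codon-usage bias that differs between core and
  non-core genes;
* per-genome feature tables with planted monotone (Spearman) correlations
  against genome size.

Open mode uses an exchangeable occurrence-probability model: each accessory
family f receives an occurrence probability p_f drawn from a Poisson process
with intensity A * p**(-1-gamma) dp on (p_min, 1], A = kappa / Gamma(1-gamma),
and every genome carries f independently with probability p_f.  Under this
model the expected number of previously unseen families contributed by the
i-th genome is ~ kappa * i**(gamma-1) (Poisson-distributed), and because the
model is exchangeable the same power law holds along *any* genome ordering,
so the planted exponent is recoverable from rarefied (randomly permuted)
curves, not just the generation order.

Codon evolution is a per-codon proposal process: proposals pick one of the
nine single-nucleotide changes uniformly; synonymous proposals are always
accepted, nonsynonymous ones with probability omega, and proposals creating
a stop codon are rejected.  With proposal rate 3*ks_branch per codon the
accepted synonymous events per synonymous (Nei-Gojobori) site equal
ks_branch, so pairwise divergence across a two-branch star is calibrated to
ks_target and the realized Ka/Ks ratio to omega_target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import gamma as _gamma_fn

from ._genetics import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    SENSE_INDEX,
    SYNONYMOUS_FAMILIES,
    single_mutants,
    translate_cds,
)

__all__ = [
    "PanGenomeModel",
    "EvolutionModel",
    "GeneRecord",
    "SyntheticDataset",
    "codon_usage_distribution",
    "sample_codon_counts",
    "sample_pan_structure",
    "simulate_codon_pair",
    "generate_pangenome",
    "generate_feature_table",
]

# ---------------------------------------------------------------------------
# precomputed substitution tables over the 61 sense codons

_N_SENSE = len(SENSE_CODONS)
#: [codon, 3*pos + alt] -> index of mutated sense codon, or -1 for a stop
_MUT_TARGET = np.full((_N_SENSE, 9), -1, dtype=np.int16)
_MUT_SYNONYMOUS = np.zeros((_N_SENSE, 9), dtype=bool)

for _ci, _codon in enumerate(SENSE_CODONS):
    _slot = 0
    for _pos, _nt, _mut in single_mutants(_codon):
        _aa = CODON_TO_AA.get(_mut)
        if _aa is not None:
            _MUT_TARGET[_ci, _slot] = SENSE_INDEX[_mut]
            _MUT_SYNONYMOUS[_ci, _slot] = _aa == CODON_TO_AA[_codon]
        _slot += 1

#: per codon: sense nonsynonymous single-mutation neighbours, used to
#: redirect proposals that would create a stop (keeps the realized
#: nonsynonymous rate equal to the rate the NG site counting implies,
#: where stop-adjacent changes count as nonsynonymous sites)
_NONSYN_NEIGHBOURS: list[np.ndarray] = []
for _ci, _codon in enumerate(SENSE_CODONS):
    _nb = [
        SENSE_INDEX[_mut]
        for _, _, _mut in single_mutants(_codon)
        if _mut in CODON_TO_AA and CODON_TO_AA[_mut] != CODON_TO_AA[_codon]
    ]
    _NONSYN_NEIGHBOURS.append(np.array(_nb, dtype=np.int16))

_CODON_ARRAY = np.array(SENSE_CODONS)

#: fixed per-codon preference scores for codon-usage bias; a model constant,
#: not per-run randomness (deliberately not expressible as a product of
#: per-position nucleotide preferences, so planted bias is visible to the
#: positional-nucleotide null model)
_CODON_PREFERENCE = np.random.default_rng(777).standard_normal(_N_SENSE)

_ATG_INDEX = SENSE_INDEX["ATG"]


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class PanGenomeModel:
    """Family-content model for a synthetic pan-genome.

    Parameters
    ----------
    n_genomes:
        Number of genomes (>= 2).
    core_families:
        Families present in every genome (>= 1).
    openness_mode:
        ``"open"`` (Heaps power-law accumulation) or ``"closed"``
        (finite family pool, saturating accumulation).
    heaps_kappa, heaps_gamma:
        Open mode: genome i contributes ~ kappa * i**(gamma-1) previously
        unseen families in expectation; gamma in (0, 1).
    pool_size:
        Closed mode: total size of the finite family pool (>= core_families).
    occupancy_range:
        Closed mode: each non-core pool family is carried by each genome
        independently with a probability drawn once from this range.  The
        default (0.2, 0.8) saturates the pan curve by ~20 genomes.
    mean_length_codons, min_length_codons:
        Gamma-distributed gene lengths (codons).
    seed:
        Seed for all family-structure randomness.
    """

    n_genomes: int
    core_families: int = 400
    openness_mode: str = "open"
    heaps_kappa: float = 150.0
    heaps_gamma: float = 0.3
    pool_size: int = 600
    occupancy_range: tuple[float, float] = (0.2, 0.8)
    mean_length_codons: int = 150
    min_length_codons: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.core_families < 1:
            raise ValueError("core_families must be >= 1")
        if self.openness_mode not in ("open", "closed"):
            raise ValueError(f"unknown openness_mode {self.openness_mode!r}")
        if self.openness_mode == "open" and not (0.0 < self.heaps_gamma < 1.0):
            raise ValueError("heaps_gamma must lie in (0, 1) for open mode")
        if self.openness_mode == "open" and self.heaps_kappa <= 0:
            raise ValueError("heaps_kappa must be positive for open mode")
        if self.openness_mode == "closed" and self.pool_size < self.core_families:
            raise ValueError("pool_size must be >= core_families for closed mode")
        if self.min_length_codons < 2 or self.mean_length_codons < self.min_length_codons:
            raise ValueError("need mean_length_codons >= min_length_codons >= 2")


@dataclass(frozen=True)
class EvolutionModel:
    """Codon-level divergence model.

    omega_target is the true nonsynonymous/synonymous rate ratio; ks_target
    the synonymous divergence per synonymous site between any two genome
    copies of a family; the codon-bias strengths skew ancestral codon choice
    within synonymous families for core and non-core genes respectively.
    """

    omega_target: float = 0.2
    ks_target: float = 0.5
    core_codon_bias: float = 2.0
    noncore_codon_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega_target < 0:
            raise ValueError("omega_target must be >= 0")
        if self.ks_target < 0:
            raise ValueError("ks_target must be >= 0")
        # Jukes-Cantor is undefined at p >= 3/4; keep expected per-site
        # divergence clearly below saturation.
        if self.ks_target > 1.0:
            raise ValueError(
                "ks_target > 1.0 saturates the Jukes-Cantor correction "
                "(uncorrected p approaches 3/4); choose ks_target <= 1.0"
            )
        if min(self.core_codon_bias, self.noncore_codon_bias) < 0:
            raise ValueError("codon bias strengths must be >= 0")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    family_id: str
    cds: str
    protein: str


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth.

    ``genes`` maps genome id to its gene records; ``truth_genes`` and
    ``truth_families`` are the generator's truth tables; ``write`` emits the
    on-disk layout (per-genome protein and CDS FASTA, truth TSVs, echoed
    model config).
    """

    model: PanGenomeModel
    evolution: EvolutionModel
    genes: dict[str, list[GeneRecord]]
    truth_genes: pd.DataFrame
    truth_families: pd.DataFrame

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genes)

    def protein_records(self) -> list[tuple[str, str, str]]:
        """(gene_id, genome_id, protein sequence) for every gene."""
        return [(g.gene_id, g.genome_id, g.protein) for recs in self.genes.values() for g in recs]

    def cds_by_gene(self) -> dict[str, str]:
        return {g.gene_id: g.cds for recs in self.genes.values() for g in recs}

    def true_pan_matrix(self) -> pd.DataFrame:
        """Family x genome presence-count matrix from the truth table."""
        mat = self.truth_genes.pivot_table(
            index="family_id", columns="genome_id", values="gene_id", aggfunc="count", fill_value=0
        )
        return mat.reindex(columns=self.genome_ids, fill_value=0).astype(int)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for genome_id, recs in self.genes.items():
            faa = outdir / f"{genome_id}.faa"
            fna = outdir / f"{genome_id}.fna"
            write_fasta(faa, [(g.gene_id, g.protein) for g in recs])
            write_fasta(fna, [(g.gene_id, g.cds) for g in recs])
            paths[f"{genome_id}.faa"] = faa
            paths[f"{genome_id}.fna"] = fna
        self.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.truth_families.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)
        cfg = {
            "pan_genome_model": {k: getattr(self.model, k) for k in self.model.__dataclass_fields__},
            "evolution_model": {k: getattr(self.evolution, k) for k in self.evolution.__dataclass_fields__},
        }
        cfg["pan_genome_model"]["occupancy_range"] = list(self.model.occupancy_range)
        with open(outdir / "model.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        paths["truth_genes.tsv"] = outdir / "truth_genes.tsv"
        paths["truth_families.tsv"] = outdir / "truth_families.tsv"
        paths["model.yaml"] = outdir / "model.yaml"
        return paths


# ---------------------------------------------------------------------------
# codon-usage machinery


def codon_usage_distribution(bias: float) -> np.ndarray:
    """Probability vector over the 61 sense codons at a given bias strength.

    Amino acids are weighted uniformly; within each synonymous family codon
    c gets weight exp(bias * z_c) for a fixed preference score z_c.  bias=0
    gives the uniform-within-family distribution.
    """
    weights = np.zeros(_N_SENSE)
    for codons in SYNONYMOUS_FAMILIES.values():
        idx = np.array([SENSE_INDEX[c] for c in codons])
        w = np.exp(bias * _CODON_PREFERENCE[idx])
        weights[idx] = w / w.sum() / len(SYNONYMOUS_FAMILIES)
    return weights / weights.sum()


def sample_codon_counts(n_codons: int, bias: float, rng: np.random.Generator) -> np.ndarray:
    """Multinomial codon counts from the biased usage distribution.

    This is the count-level view of ancestral codon sampling; it is what the
    relative-entropy analyses see, at a fraction of the cost of generating
    sequences.
    """
    return rng.multinomial(n_codons, codon_usage_distribution(bias))


# ---------------------------------------------------------------------------
# family structure


def sample_pan_structure(model: PanGenomeModel, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Presence matrix (families x genomes, 0/1) under the family model.

    Families with zero realized occurrences are dropped.  Row order: core
    families first, then accessory in sampling order.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = model.n_genomes
    genome_ids = [f"G{i + 1:03d}" for i in range(n)]

    blocks = [np.ones((model.core_families, n), dtype=np.int8)]
    if model.openness_mode == "open":
        gamma = model.heaps_gamma
        a_intensity = model.heaps_kappa / _gamma_fn(1.0 - gamma)
        p_min = 1.0 / (4.0 * n)
        total_mass = a_intensity * (p_min**-gamma - 1.0) / gamma
        n_acc = int(rng.poisson(total_mass))
        # inverse-CDF sample of the p**(-1-gamma) intensity on (p_min, 1]
        u = rng.random(n_acc)
        probs = (p_min**-gamma - u * (p_min**-gamma - 1.0)) ** (-1.0 / gamma)
        blocks.append((rng.random((n_acc, n)) < probs[:, None]).astype(np.int8))
    else:
        n_acc = model.pool_size - model.core_families
        lo, hi = model.occupancy_range
        probs = rng.uniform(lo, hi, size=n_acc)
        blocks.append((rng.random((n_acc, n)) < probs[:, None]).astype(np.int8))

    presence = np.vstack(blocks)
    realized = presence.sum(axis=1) > 0
    presence = presence[realized]
    family_ids = [f"F{i + 1:05d}" for i in range(presence.shape[0])]
    return pd.DataFrame(presence, index=family_ids, columns=genome_ids)


def classify_presence(presence: pd.DataFrame) -> pd.Series:
    """core / accessory / unique label per family from realized presence."""
    n = presence.shape[1]
    occ = (presence.to_numpy() > 0).sum(axis=1)
    labels = np.where(occ == n, "core", np.where(occ == 1, "unique", "accessory"))
    return pd.Series(labels, index=presence.index, name="family_class")


# ---------------------------------------------------------------------------
# codon evolution


def _sample_ancestor(length: int, bias: float, rng: np.random.Generator) -> np.ndarray:
    seq = rng.choice(_N_SENSE, size=length, p=codon_usage_distribution(bias))
    seq[0] = _ATG_INDEX
    return seq.astype(np.int16)


def _evolve(seq: np.ndarray, ks_branch: float, omega: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a codon-index sequence along one branch.

    Proposal rate is 3*ks_branch per codon so accepted synonymous events per
    synonymous site equal ks_branch (see module docstring).
    """
    out = seq.copy()
    lam = 3.0 * ks_branch
    if lam <= 0:
        return out
    n_events = rng.poisson(lam, size=out.size)
    hot = np.nonzero(n_events)[0]
    total = int(n_events[hot].sum())
    slots = rng.integers(0, 9, size=total)
    accept = rng.random(total)
    t = 0
    for i in hot:
        c = int(out[i])
        for _ in range(int(n_events[i])):
            slot = slots[t]
            target = _MUT_TARGET[c, slot]
            if target >= 0:
                if _MUT_SYNONYMOUS[c, slot]:
                    c = int(target)
                elif accept[t] < omega:
                    c = int(target)
            elif accept[t] < omega:
                # stop-bound proposal: redirect to a viable nonsynonymous
                # neighbour so the nonsynonymous rate matches site counting
                nb = _NONSYN_NEIGHBOURS[c]
                if nb.size:
                    c = int(nb[rng.integers(nb.size)])
            t += 1
        out[i] = c
    return out


def _indices_to_cds(seq: np.ndarray) -> str:
    return "".join(_CODON_ARRAY[seq])


def simulate_codon_pair(
    length_codons: int, evo: EvolutionModel, rng: np.random.Generator
) -> tuple[str, str]:
    """Two CDS diverged across a two-branch star at the model's targets."""
    ancestor = _sample_ancestor(length_codons, evo.noncore_codon_bias, rng)
    branch = evo.ks_target / 2.0
    a = _evolve(ancestor, branch, evo.omega_target, rng)
    b = _evolve(ancestor, branch, evo.omega_target, rng)
    return _indices_to_cds(a), _indices_to_cds(b)


# ---------------------------------------------------------------------------
# dataset generation


def generate_pangenome(model: PanGenomeModel, evo: EvolutionModel) -> SyntheticDataset:
    """Generate a full synthetic dataset (sequences + truth tables).

    Each realized family has an ancestral CDS drawn from the codon-usage
    distribution of its class (core bias for core families, non-core bias
    otherwise); every genome copy evolves independently from the ancestor
    along its own branch (ks_target/2 per branch).
    """
    rng_structure = np.random.default_rng(model.seed)
    rng_seq = np.random.default_rng(evo.seed + 1_000_003)

    presence = sample_pan_structure(model, rng_structure)
    classes = classify_presence(presence)
    genome_ids = list(presence.columns)
    branch = evo.ks_target / 2.0

    mean, minimum = model.mean_length_codons, model.min_length_codons
    shape = 4.0
    lengths = np.maximum(
        minimum, np.round(rng_structure.gamma(shape, (mean - minimum) / shape, size=presence.shape[0]) + minimum)
    ).astype(int)

    genes: dict[str, list[GeneRecord]] = {g: [] for g in genome_ids}
    truth_rows = []
    fam_rows = []
    presence_arr = presence.to_numpy()
    for fi, family_id in enumerate(presence.index):
        bias = evo.core_codon_bias if classes.iloc[fi] == "core" else evo.noncore_codon_bias
        ancestor = _sample_ancestor(int(lengths[fi]), bias, rng_seq)
        fam_rows.append(
            {
                "family_id": family_id,
                "family_class": classes.iloc[fi],
                "omega_true": evo.omega_target,
                "length_codons": int(lengths[fi]),
            }
        )
        for gi in np.nonzero(presence_arr[fi])[0]:
            genome_id = genome_ids[gi]
            evolved = _evolve(ancestor, branch, evo.omega_target, rng_seq)
            cds = _indices_to_cds(evolved)
            gene_id = f"{genome_id}|{family_id}|1"
            genes[genome_id].append(GeneRecord(gene_id, genome_id, family_id, cds, translate_cds(cds)))
            truth_rows.append({"gene_id": gene_id, "genome_id": genome_id, "family_id": family_id})

    return SyntheticDataset(
        model=model,
        evolution=evo,
        genes=genes,
        truth_genes=pd.DataFrame(truth_rows),
        truth_families=pd.DataFrame(fam_rows),
    )


# ---------------------------------------------------------------------------
# feature tables


def _as_sign(direction) -> int:
    if direction in (1, +1, "positive", "+", "pos"):
        return 1
    if direction in (-1, "negative", "-", "neg"):
        return -1
    raise ValueError(f"direction must be +/-1 or 'positive'/'negative', got {direction!r}")


def generate_feature_table(
    n_genomes: int,
    planted: list[tuple[str, float, object]],
    seed: int = 0,
    size_range_bp: tuple[int, int] = (1_700_000, 3_300_000),
) -> pd.DataFrame:
    """Per-genome feature table with planted Spearman correlations.

    ``planted`` lists (feature_name, rho_target in [0, 1], direction).  A
    target of 1 is a pure monotone transform of genome size (realized rho
    exactly +/-1); intermediate targets use a Gaussian copula with Pearson
    parameter 2*sin(pi*rho_s/6), whose Spearman correlation is rho_s; a
    target of 0 is an independent column.  The genome-size range default
    spans the observed bacterial sizes the feature model emulates (1.7-3.3
    Mb).
    """
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_range_bp[0], size_range_bp[1], size=n_genomes, endpoint=True)
    table = pd.DataFrame(
        {"genome_id": [f"G{i + 1:03d}" for i in range(n_genomes)], "genome_size_bp": sizes}
    )
    ranks = pd.Series(sizes).rank(method="average").to_numpy()
    z_size = _normal_scores(ranks)
    for name, rho_target, direction in planted:
        if not 0.0 <= rho_target <= 1.0:
            raise ValueError(f"|rho target| must be <= 1, got {rho_target} for {name!r}")
        sign = _as_sign(direction)
        if rho_target == 1.0:
            col = sign * (sizes / 1000.0 + 0.25 * (sizes / 1000.0) ** 1.5)
        elif rho_target == 0.0:
            col = rng.standard_normal(n_genomes)
        else:
            rho_p = 2.0 * math.sin(math.pi * rho_target / 6.0)
            col = sign * (rho_p * z_size + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(n_genomes))
        table[name] = col
    return table


def _normal_scores(ranks: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf((ranks - 0.5) / len(ranks))
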