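"""Synthetic selection and FidelitySeq data with known ground truth.

The raw sequencing data behind the ribozyme landscape are not publicly
deposited, so every analysis stage here is exercised against generated
data that carries the statistical structure the analyses assume:

* a mutagenized library dominated by low-order mutants over a 5TU-like
  (152 nt) or t1-like (124 nt) reference;
* a true fitness landscape with additive single effects drawn from a
  neutral / deleterious / lethal mixture, plus pairwise terms confined to
  annotated base pairs (pair-restoring combinations positive, G·U wobbles
  partially rescued) and a fitness floor;
* one round of exponential selection (post ∝ pre · e^{s·f}) sampled
  multinomially at configured depth, with uniform per-base substitution
  sequencing error;
* a toy atomic model placing paired residues in contact (< 8 Å) and all
  other residues far apart (≥ 15 Å), so distance-decay recovery is
  testable;
* FidelitySeq reads with anchors, a randomized substrate k-mer and a
  known per-position misincorporation vector.

All generators are deterministic given their seed, and truth tables
always accompany generated reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
import pandas as pd

from .epistasis import SecondaryStructure, classify_bases
from .fidelity_seq import FORWARD, REVERSE, FidelityDesign, revcomp
from .genotype_calling import (
    DELETION,
    Genotype,
    Mutation,
    Reference,
    to_dna,
)
from .structure_map import ChainMap, StructureModel, read_structure

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LandscapeConfig:
    """True-landscape generator settings.

    Single-mutant effects are a mixture: neutral N(0, sigma_neutral),
    deleterious N(mu_deleterious, sigma_deleterious), and a lethal point
    mass at the fitness floor f_min.  Substitutions that turn an annotated
    Watson-Crick pair into a G·U wobble have their effect scaled by
    (1 - wobble_rescue): wobbles partially preserve helix geometry.
    Double-mutant pair terms are +pair_term for mutant combinations that
    restore a Watson-Crick pair at an annotated position pair,
    +pair_term * wobble_rescue for wobble-restoring combinations, and 0
    otherwise (including all unpaired position pairs).
    """

    seed: int
    subunit_id: str = "5TU"
    length: int = 152  # 5TU-like; use 124 for a t1-like subunit
    n_stems: int = 8
    stem_length: int = 4
    p_neutral: float = 0.30
    sigma_neutral: float = 0.10
    p_deleterious: float = 0.55
    mu_deleterious: float = -2.0
    sigma_deleterious: float = 0.8
    p_lethal: float = 0.15
    f_min: float = -5.0
    pair_term: float = 2.0
    wobble_rescue: float = 0.5
    n_doubles: int = 5000
    # library doping rate; informs which genotypes exist, not class weights
    mutation_rate: float = 0.003
    max_order: int = 2

    def __post_init__(self) -> None:
        probs = (self.p_neutral, self.p_deleterious, self.p_lethal)
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError("mixture probabilities must sum to 1")
        if any(p < 0 for p in probs) or not 0 <= self.wobble_rescue <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.f_min > 0:
            raise ValueError("fitness floor must be <= 0")
        if min(self.sigma_neutral, self.sigma_deleterious) < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass
class SelectionConfig:
    """One-round selection and sequencing settings.

    Pre-selection class fractions put substantial mass on doubles so that
    epistasis is measurable at desk-scale depth; a realistically doped
    library would leave doubles at ~2% of reads.
    """

    seed: int
    n_replicates: int = 3
    depth: int = 500_000
    selection_strength: float = 1.0
    error_rate: float = 1e-3
    wt_fraction: float = 0.2
    single_fraction: float = 0.4
    double_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.depth < 1 or self.n_replicates < 1:
            raise ValueError("depth and replicates must be >= 1")
        if not math.isfinite(self.selection_strength):
            raise ValueError("selection strength must be finite")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must lie in [0, 1)")
        if not math.isclose(
            self.wt_fraction + self.single_fraction + self.double_fraction, 1.0, abs_tol=1e-9
        ):
            raise ValueError("class fractions must sum to 1")


# ---------------------------------------------------------------------------
# landscape


@dataclass
class Landscape:
    """A true fitness landscape with its reference, structure and toy model."""

    reference: Reference
    structure: SecondaryStructure
    structure_model: StructureModel
    fitness: dict[Genotype, float]
    config: LandscapeConfig

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {"genotype_label": g.label, "hamming": g.hamming, "f_true": f}
            for g, f in self.fitness.items()
        ]
        return pd.DataFrame(rows).set_index("genotype_label")

    @property
    def genotypes(self) -> list[Genotype]:
        return list(self.fitness)


def _stem_pairs(length: int, n_stems: int, stem_length: int) -> list[tuple[int, int]]:
    """Disjoint (i, j) base pairs arranged as short stems spread over the
    sequence: stem s occupies block s of size length//n_stems."""
    block = length // n_stems
    if block < 2 * stem_length + 4:
        raise ValueError("sequence too short for requested stems")
    pairs = []
    for s in range(n_stems):
        base = s * block
        for t in range(stem_length):
            i = base + 3 + t
            j = base + block - 3 - t
            pairs.append((i, j))
    return pairs


def _toy_structure_model(
    subunit_id: str, length: int, pairs: Sequence[tuple[int, int]], sequence: str
) -> StructureModel:
    """One-residue-per-position toy model: partners of an annotated pair sit
    5 Å apart in a private cluster; every other residue pair is >= 35 Å."""
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    cluster_of: dict[int, int] = {}
    next_cluster = 0
    for pos in range(1, length + 1):
        if pos in cluster_of:
            continue
        cluster_of[pos] = next_cluster
        if pos in partner:
            cluster_of[partner[pos]] = next_cluster
        next_cluster += 1

    def center(c: int) -> np.ndarray:
        return np.array([40.0 * (c % 12), 40.0 * ((c // 12) % 12), 40.0 * (c // 144)])

    for pos in range(1, length + 1):
        c = center(cluster_of[pos])
        offset = np.zeros(3)
        if pos in partner:
            offset = np.array([0.0, 2.5, 0.0]) * (1 if pos < partner[pos] else -1)
        res = gemmi.Residue()
        res.name = sequence[pos - 1].replace("T", "U")
        res.seqid = gemmi.SeqId(pos, " ")
        for name, extra in (("C1'", np.zeros(3)), ("P", np.array([0.0, 0.0, 1.5]))):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element("C" if name == "C1'" else "P")
            xyz = c + offset + extra
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    # round-trip through the reader so the toy model behaves exactly like a
    # parsed file (heavy atoms, altloc resolution, mapping)
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as fh:
        path = fh.name
    st.setup_entities()
    st.write_pdb(path)
    parsed = read_structure(path, {"A": ChainMap(subunit_id, 0)})
    Path(path).unlink()
    return parsed


def simulate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Draw a true landscape: reference, structure, toy model, fitness map.

    The wild type scores exactly 0.  Singles cover every substitution at
    every position; doubles cover all 9 substitution combinations at every
    annotated pair plus random position pairs up to ``n_doubles``.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs = _stem_pairs(cfg.length, cfg.n_stems, cfg.stem_length)
    seq = list(rng.choice(list(_BASES), size=cfg.length))
    for i, j in pairs:  # make annotated pairs Watson-Crick in the wild type
        seq[j - 1] = _COMPLEMENT[seq[i - 1]]
    sequence = "".join(seq)
    ref = Reference(cfg.subunit_id, sequence)
    structure = SecondaryStructure(
        [((cfg.subunit_id, i), (cfg.subunit_id, j), "intra-helix") for i, j in pairs]
    )
    model = _toy_structure_model(cfg.subunit_id, cfg.length, pairs, sequence)

    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    fitness: dict[Genotype, float] = {Genotype(cfg.subunit_id): 0.0}
    single_effect: dict[tuple[int, str], float] = {}
    for pos in range(1, cfg.length + 1):
        ref_base = ref.base(pos)
        for alt in _BASES:
            if alt == ref_base:
                continue
            cat = rng.choice(3, p=[cfg.p_neutral, cfg.p_deleterious, cfg.p_lethal])
            if cat == 0:
                f = rng.normal(0.0, cfg.sigma_neutral)
            elif cat == 1:
                f = rng.normal(cfg.mu_deleterious, cfg.sigma_deleterious)
            else:
                f = cfg.f_min
            if pos in partner:
                other = ref.base(partner[pos])
                if classify_bases(alt, other) == "wobble_pair":
                    f *= 1.0 - cfg.wobble_rescue
            f = max(f, cfg.f_min)
            single_effect[(pos, alt)] = f
            g = Genotype(cfg.subunit_id, (Mutation(pos, ref_base, alt),))
            fitness[g] = f

    def pair_epsilon(p1: int, a1: str, p2: int, a2: str) -> float:
        if partner.get(p1) != p2:
            return 0.0
        cls = classify_bases(a1, a2)
        if cls == "WC_pair":
            return cfg.pair_term
        if cls == "wobble_pair":
            return cfg.pair_term * cfg.wobble_rescue
        return 0.0

    def add_double(p1: int, a1: str, p2: int, a2: str) -> None:
        g = Genotype(
            cfg.subunit_id,
            (Mutation(p1, ref.base(p1), a1), Mutation(p2, ref.base(p2), a2)),
        )
        if g in fitness:
            return
        f = single_effect[(p1, a1)] + single_effect[(p2, a2)] + pair_epsilon(p1, a1, p2, a2)
        fitness[g] = max(f, cfg.f_min)

    # all substitution combinations at annotated pairs
    for i, j in pairs:
        for a1 in _BASES:
            if a1 == ref.base(i):
                continue
            for a2 in _BASES:
                if a2 == ref.base(j):
                    continue
                add_double(i, a1, j, a2)
    # random doubles up to n_doubles
    n_target = max(cfg.n_doubles, sum(1 for g in fitness if g.hamming == 2))
    attempts = 0
    while sum(1 for g in fitness if g.hamming == 2) < n_target and attempts < 50 * n_target:
        attempts += 1
        p1, p2 = sorted(rng.choice(cfg.length, size=2, replace=False) + 1)
        a1 = _BASES[rng.integers(4)]
        a2 = _BASES[rng.integers(4)]
        if a1 == ref.base(int(p1)) or a2 == ref.base(int(p2)):
            continue
        add_double(int(p1), a1, int(p2), a2)
    return Landscape(ref, structure, model, fitness, cfg)


# ---------------------------------------------------------------------------
# selection reads


@dataclass
class SimulatedSelection:
    """Generated FASTQ paths plus the accompanying truth tables."""

    fastq_paths: dict[tuple[str, str], Path]
    truth_counts: pd.DataFrame  # genotype_label x (replicate, phase) true counts
    truth_fitness: pd.DataFrame
    replicates: list[str]


def _class_frequencies(landscape: Landscape, cfg: SelectionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pre- and post-selection genotype frequencies under the class-fraction
    library model and one round of exponential selection."""
    genotypes = landscape.genotypes
    hamming = np.array([g.hamming for g in genotypes])
    freqs = np.zeros(len(genotypes))
    freqs[hamming == 0] = cfg.wt_fraction
    n_single = int((hamming == 1).sum())
    n_double = int((hamming == 2).sum())
    if n_single:
        freqs[hamming == 1] = cfg.single_fraction / n_single
    if n_double:
        freqs[hamming == 2] = cfg.double_fraction / n_double
    freqs /= freqs.sum()
    f_true = np.array([landscape.fitness[g] for g in genotypes])
    post_w = freqs * np.exp(cfg.selection_strength * f_true)
    return freqs, post_w / post_w.sum()


def simulate_selection_counts(landscape: Landscape, cfg: SelectionConfig):
    """Multinomial pre/post count table straight from the true landscape.

    Skips read rendering and genotype calling entirely: counts are exact
    (no sequencing error, no read misassignment), which is the right input
    for testing the calibration of downstream inference.
    """
    from .genotype_calling import CountTable

    rng = np.random.default_rng(cfg.seed)
    freqs, post_freqs = _class_frequencies(landscape, cfg)
    genotypes = landscape.genotypes
    replicates = [f"rep{i + 1}" for i in range(cfg.n_replicates)]
    cols = {}
    for rep in replicates:
        cols[(rep, "pre")] = rng.multinomial(cfg.depth, freqs)
        cols[(rep, "post")] = rng.multinomial(cfg.depth, post_freqs)
    counts = pd.DataFrame(
        cols, index=pd.Index([g.label for g in genotypes], name="genotype_label")
    )
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["replicate", "phase"])
    return CountTable(counts, {g.label: g for g in genotypes}, landscape.reference.subunit_id)


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def _mutate_reads(seq_matrix: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitution errors on a (reads x L) uint8 base matrix."""
    if error_rate <= 0:
        return
    total = seq_matrix.size
    n_err = rng.binomial(total, error_rate)
    if n_err == 0:
        return
    # sampling with replacement then dedup: collisions are negligible at
    # realistic error rates and depths
    flat_idx = np.unique(rng.integers(0, total, size=n_err))
    flat = seq_matrix.reshape(-1)
    codes = _CODE_OF[flat[flat_idx]]
    shifts = rng.integers(1, 4, size=flat_idx.size).astype(np.uint8)
    flat[flat_idx] = _BASE_CODES[(codes + shifts) % 4]


def _write_fastq(path: Path, seq_matrix_rows: list[np.ndarray], prefix: str) -> int:
    """Write rows (uint8 base arrays) as a FASTQ with constant quality."""
    n = 0
    with open(path, "w") as fh:
        for block in seq_matrix_rows:
            for row in block:
                seq = row.tobytes().decode()
                fh.write(f"@{prefix}:{n}\n{seq}\n+\n{'I' * len(seq)}\n")
                n += 1
    return n


def simulate_selection_reads(
    landscape: Landscape, cfg: SelectionConfig, outdir: Union[str, Path]
) -> SimulatedSelection:
    """Simulate pre/post selection FASTQ files for each replicate.

    Pre counts ~ Multinomial(depth, library frequencies); post counts ~
    Multinomial(depth, frequencies ∝ pre_freq · exp(s · f_true)).  Reads
    are the genotype sequences with independent per-base substitution
    errors.  Truth tables (counts and fitness) are written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genotypes = landscape.genotypes
    freqs, post_freqs = _class_frequencies(landscape, cfg)

    # genotype sequences as a ragged list of uint8 arrays (deletions shorten)
    seqs = [
        np.frombuffer(g.sequence(landscape.reference).encode(), dtype=np.uint8)
        for g in genotypes
    ]
    replicates = [f"rep{i + 1}" for i in range(cfg.n_replicates)]
    fastq_paths: dict[tuple[str, str], Path] = {}
    count_cols = {}
    for rep in replicates:
        for phase, probs in (("pre", freqs), ("post", post_freqs)):
            counts = rng.multinomial(cfg.depth, probs)
            blocks = []
            for gi in np.nonzero(counts)[0]:
                block = np.tile(seqs[gi], (counts[gi], 1))
                _mutate_reads(block, cfg.error_rate, rng)
                blocks.append(block)
            path = outdir / f"{rep}_{phase}.fastq"
            _write_fastq(path, blocks, prefix=f"{rep}:{phase}")
            fastq_paths[(rep, phase)] = path
            count_cols[(rep, phase)] = counts
    labels = [g.label for g in genotypes]
    truth_counts = pd.DataFrame(
        count_cols, index=pd.Index(labels, name="genotype_label")
    )
    truth_counts.columns = pd.MultiIndex.from_tuples(
        truth_counts.columns, names=["replicate", "phase"]
    )
    truth_fitness = landscape.truth_table()
    truth_fitness.to_csv(outdir / "truth_fitness.tsv", sep="\t")
    flat = truth_counts.copy()
    flat.columns = [f"{r}_{p}" for r, p in flat.columns]
    flat.to_csv(outdir / "truth_counts.tsv", sep="\t")
    return SimulatedSelection(fastq_paths, truth_counts, truth_fitness, replicates)


# ---------------------------------------------------------------------------
# fidelity reads


def simulate_fidelity_reads(
    design: FidelityDesign,
    errors: Sequence[float],
    n: int,
    seed: int,
    kmer_weights: Optional[dict[str, float]] = None,
    out_path: Optional[Union[str, Path]] = None,
) -> list[str]:
    """Simulate FidelitySeq reads with a known per-position error vector.

    Substrate position p (N1..Nk, 5'->3') mismatches its encoded base with
    probability errors[p-1], the erroneous base uniform over the three
    alternatives.  ``kmer_weights`` multiplies the resulting k-mer
    distribution (emulating, e.g., depletion of AU-rich substrates).
    Reads are anchor5 + product k-mer + anchor3; with ``out_path`` a FASTQ
    (phred 33, constant quality) is also written, byte-identical for a
    given seed.
    """
    if len(errors) != design.k:
        raise ValueError("error vector length must equal k")
    rng = np.random.default_rng(seed)
    expected = design.substrate_kmer(design.expected_product)  # N1..Nk
    from .fidelity_seq import _all_kmers

    kmers = _all_kmers(design.k)
    probs = np.empty(len(kmers))
    for idx, km in enumerate(kmers):
        p = 1.0
        for pos, base in enumerate(km):
            e = errors[pos]
            p *= (1.0 - e) if base == expected[pos] else e / 3.0
        if kmer_weights is not None:
            p *= kmer_weights.get(km, kmer_weights.get(km.replace("T", "U"), 1.0))
        probs[idx] = p
    if probs.sum() <= 0:
        raise ValueError("k-mer distribution has zero mass")
    probs /= probs.sum()
    counts = rng.multinomial(n, probs)
    reads: list[str] = []
    for idx in np.nonzero(counts)[0]:
        substrate = kmers[idx]
        product = substrate if design.mode == FORWARD else substrate[::-1]
        read = design.anchor5 + product + design.anchor3
        reads.extend([read] * int(counts[idx]))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    if out_path is not None:
        with open(out_path, "w") as fh:
            for i, read in enumerate(reads):
                fh.write(f"@fid:{i}\n{read}\n+\n{'I' * len(read)}\n")
    return reads
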