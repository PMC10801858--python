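"""Genotype calling from selection sequencing reads.

Turns merged, reference-oriented reads into genotypes (ordered sets of
substitutions and single-nucleotide deletions relative to a wild-type
subunit reference) and tabulates pre-/post-selection counts.

Coordinates are 1-based, 5'->3', per subunit, matching the field's labels
for this ribozyme (e.g. the active-site cytidine C43, or the
activity-enhancing t5 mutations dU38 and C110U).  Sequences are stored
internally in the DNA alphabet (U normalized to T); labels are rendered in
the RNA alphabet.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DELETION = "-"
_DNA = frozenset("ACGT")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_DNA_TO_RNA = str.maketrans("T", "U")

PHASES = ("pre", "post")


def to_dna(seq: str) -> str:
    """Normalize an RNA/DNA string to the internal uppercase DNA alphabet."""
    return seq.translate(_RNA_TO_DNA).upper()


def to_rna(seq: str) -> str:
    return seq.translate(_DNA_TO_RNA)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Reference:
    """A wild-type subunit reference sequence.

    Position 1 is the 5'-most nucleotide.
    """

    subunit_id: str
    sequence: str  # DNA alphabet, uppercase

    def __post_init__(self) -> None:
        seq = to_dna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"non-nucleotide characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position (DNA alphabet)."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class Mutation:
    """A substitution or single-nucleotide deletion at a 1-based position."""

    position: int
    ref_base: str  # DNA alphabet
    alt: str  # DNA base, or DELETION

    def __post_init__(self) -> None:
        if self.ref_base not in _DNA:
            raise ValueError(f"invalid ref base {self.ref_base!r}")
        if self.alt not in _DNA and self.alt != DELETION:
            raise ValueError(f"invalid alt {self.alt!r}")
        if self.alt == self.ref_base:
            raise ValueError("alt equals ref base")

    @property
    def is_deletion(self) -> bool:
        return self.alt == DELETION

    @property
    def label(self) -> str:
        """Field-convention label: 'C110U' for substitutions, 'ΔU38' for deletions."""
        ref = to_rna(self.ref_base)
        if self.is_deletion:
            return f"Δ{ref}{self.position}"
        return f"{ref}{self.position}{to_rna(self.alt)}"


@dataclass(frozen=True)
class Genotype:
    """A subunit plus an ordered, position-unique set of mutations.

    The empty mutation tuple is the wild type.  Hamming distance is the
    number of mutations.
    """

    subunit_id: str
    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations, key=lambda m: m.position))
        object.__setattr__(self, "mutations", muts)
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise ValueError("two mutations share a position")

    @property
    def hamming(self) -> int:
        return len(self.mutations)

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations

    @property
    def label(self) -> str:
        if self.is_wildtype:
            return "wt"
        return ",".join(m.label for m in self.mutations)

    def sequence(self, ref: Reference) -> str:
        """Render the mutant sequence (DNA alphabet) on a reference."""
        if ref.subunit_id != self.subunit_id:
            raise ValueError("reference subunit does not match genotype subunit")
        seq = list(ref.sequence)
        for m in self.mutations:
            if ref.base(m.position) != m.ref_base:
                raise ValueError(f"mutation {m.label} inconsistent with reference")
            seq[m.position - 1] = "" if m.is_deletion else m.alt
        return "".join(seq)


def parse_mutation_label(label: str) -> Mutation:
    """Parse labels like 'C110U' or 'ΔU38' (RNA alphabet)."""
    label = label.strip()
    if label.startswith("Δ") or label.lower().startswith("del"):
        body = label[1:] if label.startswith("Δ") else label[3:]
        ref = to_dna(body[0])
        return Mutation(int(body[1:]), ref, DELETION)
    ref, alt = to_dna(label[0]), to_dna(label[-1])
    return Mutation(int(label[1:-1]), ref, alt)


def parse_genotype_label(label: str, subunit_id: str) -> Genotype:
    """Inverse of ``Genotype.label``."""
    label = label.strip()
    if label == "wt":
        return Genotype(subunit_id)
    muts = tuple(parse_mutation_label(tok) for tok in label.split(","))
    return Genotype(subunit_id, muts)


# ---------------------------------------------------------------------------
# reference I/O


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_references(fasta_path: Union[str, Path]) -> dict[str, Reference]:
    """Read all subunit references from a FASTA file, keyed by record id."""
    with _open_text(fasta_path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    refs: dict[str, Reference] = {}
    for rec in records:
        if not rec.id:
            raise ValueError("FASTA record without an identifier")
        if rec.id in refs:
            raise ValueError(f"duplicate subunit tag {rec.id!r}")
        refs[rec.id] = Reference(rec.id, str(rec.seq))
    return refs


def read_reference(fasta_path: Union[str, Path], subunit_id: Optional[str] = None) -> Reference:
    """Read a single subunit reference.

    With more than one record, ``subunit_id`` selects the subunit; a
    multi-record file without a selector is a format error.
    """
    refs = read_references(fasta_path)
    if subunit_id is None:
        if len(refs) != 1:
            raise ValueError(
                f"{len(refs)} records in {fasta_path}; pass subunit_id to select one"
            )
        return next(iter(refs.values()))
    try:
        return refs[subunit_id]
    except KeyError:
        raise ValueError(f"subunit {subunit_id!r} not found in {fasta_path}") from None


# ---------------------------------------------------------------------------
# calling


class RejectReason(str, Enum):
    EMPTY_READ = "empty_read"
    AMBIGUOUS_BASE = "ambiguous_base"
    INSERTION = "insertion"
    LONG_DELETION = "long_deletion"
    INCOMPLETE_COVERAGE = "incomplete_coverage"
    TOO_MANY_MUTATIONS = "too_many_mutations"


@dataclass(frozen=True)
class Reject:
    reason: RejectReason


@dataclass(frozen=True)
class CallParams:
    """Thresholds for read-to-genotype calling.

    max_mutations should match the expected library order: reads whose
    sequencing errors push them past it are rejected rather than assigned
    a spurious genotype.
    """

    max_mutations: int = 4
    max_deletion_length: int = 1
    # end-to-end coverage of the reference is required; terminal gaps longer
    # than max_deletion_length reject the read
    match_score: float = 1.0
    mismatch_score: float = -1.0
    open_gap_score: float = -4.0
    extend_gap_score: float = -2.0


class GenotypeCaller:
    """Calls genotypes against one reference.

    Reads of exactly reference length are called by direct positional
    comparison (the optimal global alignment under the affine scoring for
    reads with few mutations); other lengths are globally aligned with
    affine gap penalties.  Results are memoized so repeated read sequences
    (the overwhelming majority in amplicon data) are only computed once.
    """

    def __init__(self, ref: Reference, params: CallParams = CallParams(), cache_size: int = 300_000):
        self.ref = ref
        self.params = params
        self._ref_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        self._acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = params.match_score
        aligner.mismatch_score = params.mismatch_score
        aligner.open_gap_score = params.open_gap_score
        aligner.extend_gap_score = params.extend_gap_score
        self._aligner = aligner
        self._cache: dict[str, Union[Genotype, Reject]] = {}
        self._cache_size = cache_size

    def __call__(self, read: str) -> Union[Genotype, Reject]:
        read = to_dna(read)
        cached = self._cache.get(read)
        if cached is not None:
            return cached
        result = self._call(read)
        if len(self._cache) < self._cache_size:
            self._cache[read] = result
        return result

    # -- internals

    def _call(self, read: str) -> Union[Genotype, Reject]:
        if not read:
            return Reject(RejectReason.EMPTY_READ)
        if len(read) == self.ref.length:
            return self._call_equal_length(read)
        if len(read) > self.ref.length:
            # a longer read necessarily contains at least one insertion
            return Reject(RejectReason.INSERTION)
        if len(read) < self.ref.length - self.params.max_mutations:
            # cannot be explained by <= max_mutations single-nt deletions
            return Reject(RejectReason.INCOMPLETE_COVERAGE)
        return self._call_aligned(read)

    def _call_equal_length(self, read: str) -> Union[Genotype, Reject]:
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        diff = np.nonzero(arr != self._ref_arr)[0]
        if diff.size > self.params.max_mutations:
            return Reject(RejectReason.TOO_MANY_MUTATIONS)
        if diff.size and not np.isin(arr[diff], self._acgt).all():
            return Reject(RejectReason.AMBIGUOUS_BASE)
        muts = tuple(
            Mutation(int(i) + 1, self.ref.sequence[i], read[i]) for i in diff
        )
        return Genotype(self.ref.subunit_id, muts)

    def _call_aligned(self, read: str) -> Union[Genotype, Reject]:
        if set(read) - _DNA:
            return Reject(RejectReason.AMBIGUOUS_BASE)
        aln = self._aligner.align(self.ref.sequence, read)[0]
        t_blocks, q_blocks = aln.aligned
        if len(q_blocks) == 0:
            return Reject(RejectReason.INCOMPLETE_COVERAGE)
        muts: list[Mutation] = []
        prev_t, prev_q = 0, 0
        events = list(zip(t_blocks, q_blocks)) + [((self.ref.length, None), (len(read), None))]
        for (t_start, t_end), (q_start, q_end) in events:
            ins = q_start - prev_q
            dele = t_start - prev_t
            if ins > 0:
                return Reject(RejectReason.INSERTION)
            if dele > self.params.max_deletion_length:
                # multi-nt deletion, or a truncated read (terminal gap)
                reason = (
                    RejectReason.INCOMPLETE_COVERAGE
                    if prev_t == 0 or t_start == self.ref.length
                    else RejectReason.LONG_DELETION
                )
                return Reject(reason)
            for i in range(prev_t, t_start):
                muts.append(Mutation(i + 1, self.ref.sequence[i], DELETION))
            if t_end is None:
                break
            # substitutions inside the aligned block
            t_seg = self._ref_arr[t_start:t_end]
            q_seg = np.frombuffer(read.encode(), dtype=np.uint8)[q_start:q_end]
            for i in np.nonzero(t_seg != q_seg)[0]:
                pos = t_start + int(i)
                muts.append(Mutation(pos + 1, self.ref.sequence[pos], read[q_start + int(i)]))
            prev_t, prev_q = t_end, q_end
        if len(muts) > self.params.max_mutations:
            return Reject(RejectReason.TOO_MANY_MUTATIONS)
        return Genotype(self.ref.subunit_id, tuple(muts))


def call_genotype(
    read: str, ref: Reference, params: CallParams = CallParams()
) -> Union[Genotype, Reject]:
    """Call a single read against a reference (convenience wrapper)."""
    return GenotypeCaller(ref, params)(read)


def iter_fastq_sequences(path: Union[str, Path]) -> Iterator[str]:
    """Yield read sequences from a (optionally gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


# ---------------------------------------------------------------------------
# counting


@dataclass
class CountTable:
    """Per-genotype read counts indexed by (replicate, phase).

    ``counts`` is indexed by genotype label with a (replicate, phase)
    column MultiIndex; ``genotypes`` maps labels back to Genotype objects.
    """

    counts: pd.DataFrame
    genotypes: dict[str, Genotype]
    subunit_id: str

    @property
    def replicates(self) -> list[str]:
        return list(self.counts.columns.levels[0])

    @property
    def depth(self) -> pd.Series:
        """Total assigned reads per (replicate, phase)."""
        return self.counts.sum(axis=0)

    def hamming(self) -> pd.Series:
        return pd.Series(
            {lbl: g.hamming for lbl, g in self.genotypes.items()}, name="hamming"
        ).reindex(self.counts.index)

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.counts.copy()
        out.columns = [f"{rep}_{phase}" for rep, phase in out.columns]
        out.insert(0, "subunit", self.subunit_id)
        out.insert(1, "hamming", self.hamming())
        out.index.name = "genotype_label"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="genotype_label")
        subunit = str(df["subunit"].iloc[0])
        count_cols = [c for c in df.columns if c not in ("subunit", "hamming")]
        counts = df[count_cols].astype(np.int64)
        counts.columns = pd.MultiIndex.from_tuples(
            [tuple(c.rsplit("_", 1)) for c in count_cols], names=["replicate", "phase"]
        )
        genotypes = {lbl: parse_genotype_label(lbl, subunit) for lbl in counts.index}
        return cls(counts, genotypes, subunit)


def tabulate_counts(
    stream: Iterable[tuple[Genotype, str, str]],
    replicates: Iterable[str],
    phases: Iterable[str] = PHASES,
) -> CountTable:
    """Tabulate a stream of (genotype, replicate, phase) into a CountTable.

    The result is independent of stream order.  Unknown replicate or phase
    labels raise.
    """
    replicates = list(replicates)
    phases = list(phases)
    valid = {(r, p) for r in replicates for p in phases}
    counters: dict[tuple[str, str], Counter] = {key: Counter() for key in valid}
    genotypes: dict[str, Genotype] = {}
    subunit: Optional[str] = None
    for genotype, rep, phase in stream:
        if (rep, phase) not in valid:
            raise ValueError(f"unknown (replicate, phase) label ({rep!r}, {phase!r})")
        if subunit is None:
            subunit = genotype.subunit_id
        genotypes.setdefault(genotype.label, genotype)
        counters[(rep, phase)][genotype.label] += 1
    labels = sorted(genotypes)
    cols = pd.MultiIndex.from_product([replicates, phases], names=["replicate", "phase"])
    data = np.zeros((len(labels), len(cols)), dtype=np.int64)
    for j, (rep, phase) in enumerate(cols):
        ctr = counters[(rep, phase)]
        for i, lbl in enumerate(labels):
            data[i, j] = ctr.get(lbl, 0)
    counts = pd.DataFrame(data, index=pd.Index(labels, name="genotype_label"), columns=cols)
    return CountTable(counts, genotypes, subunit or "")


def count_fastq_files(
    ref: Reference,
    fastq_by_rep_phase: dict[tuple[str, str], Union[str, Path]],
    params: CallParams = CallParams(),
) -> tuple[CountTable, dict[tuple[str, str], Counter]]:
    """Call and count reads from FASTQ files keyed by (replicate, phase).

    Returns the count table and per-file reject tallies (by reason).
    """
    caller = GenotypeCaller(ref, params)
    replicates = sorted({rep for rep, _ in fastq_by_rep_phase})
    phases = sorted({ph for _, ph in fastq_by_rep_phase}, reverse=True)  # pre, post
    counters: dict[tuple[str, str], Counter] = {}
    rejects: dict[tuple[str, str], Counter] = {}
    genotypes: dict[str, Genotype] = {}
    for key, path in fastq_by_rep_phase.items():
        ctr: Counter = Counter()
        rej: Counter = Counter()
        for seq in iter_fastq_sequences(path):
            result = caller(seq)
            if isinstance(result, Reject):
                rej[result.reason.value] += 1
            else:
                lbl = result.label
                genotypes.setdefault(lbl, result)
                ctr[lbl] += 1
        counters[key] = ctr
        rejects[key] = rej
    labels = sorted(genotypes)
    cols = pd.MultiIndex.from_product([replicates, phases], names=["replicate", "phase"])
    data = np.zeros((len(labels), len(cols)), dtype=np.int64)
    index = {lbl: i for i, lbl in enumerate(labels)}
    for j, key in enumerate(cols):
        for lbl, n in counters.get(tuple(key), {}).items():
            data[index[lbl], j] = n
    counts = pd.DataFrame(data, index=pd.Index(labels, name="genotype_label"), columns=cols)
    return CountTable(counts, genotypes, ref.subunit_id), rejects


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterReport:
    n_in: int
    n_kept: int
    n_dropped_low_pre: int
    min_pre: int
    min_replicates: int


def filter_genotypes(
    table: CountTable, min_pre: int = 10, min_replicates: Optional[int] = None
) -> tuple[CountTable, FilterReport]:
    """Keep genotypes with pre-selection count >= min_pre in enough replicates.

    The wild type is always retained and must be present pre-selection in
    every replicate (fitness is undefined otherwise).
    """
    if min_pre < 1:
        raise ValueError("min_pre must be >= 1")
    reps = table.replicates
    if min_replicates is None:
        min_replicates = len(reps)
    if min_replicates > len(reps):
        raise ValueError("min_replicates exceeds number of replicates")
    pre = table.counts.xs("pre", axis=1, level="phase")
    if "wt" not in table.counts.index or (pre.loc["wt"] <= 0).any():
        raise ValueError("wild type absent from a (replicate, pre) library; fitness undefined")
    ok = (pre >= min_pre).sum(axis=1) >= min_replicates
    ok.loc["wt"] = True
    kept = table.counts.loc[ok]
    report = FilterReport(
        n_in=len(table.counts),
        n_kept=int(ok.sum()),
        n_dropped_low_pre=int((~ok).sum()),
        min_pre=min_pre,
        min_replicates=min_replicates,
    )
    genotypes = {lbl: table.genotypes[lbl] for lbl in kept.index}
    return CountTable(kept, genotypes, table.subunit_id), report
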