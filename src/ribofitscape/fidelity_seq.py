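"""FidelitySeq: per-position polymerization fidelity from deep sequencing.

Extension products carrying a randomized k-mer substrate (triplet by
default) ligated at a defined template junction are sequenced; each read
is validated by its constant flanking anchors, the incorporated k-mer is
extracted and compared position-by-position against the complement of the
template-encoded k-mer.  Fraction correct per substrate position, with
Wilson 95% intervals, yields the fidelity profile; the per-nucleotide
fidelity aggregates positions by arithmetic mean (geometric available).

Substrate positions are numbered 5'->3' as N1..Nk (N1 = 5'-most base of
the 5'-triphosphorylated substrate) in both synthesis modes.  Reads are
assumed to show the product strand 5'->3'; in the reverse (3'->5')
synthesis mode the extracted bases therefore map onto substrate positions
in reverse order.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genotype_calling import to_dna

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")

FORWARD = "forward_5to3"
REVERSE = "reverse_3to5"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FidelityRejectReason(str, Enum):
    ANCHOR_MISSING = "anchor_missing"
    WRONG_LENGTH = "wrong_length"
    AMBIGUOUS_BASE = "ambiguous_base"


@dataclass(frozen=True)
class FidelityReject:
    reason: FidelityRejectReason


@dataclass(frozen=True)
class FidelityDesign:
    """The FidelitySeq construct: template, junction and read anchors.

    ``junction`` is the 1-based template position of the first encoded
    base; ``anchor5``/``anchor3`` are the constant read flanks immediately
    surrounding the incorporated k-mer.  Anchor matching is exact by
    default: errors in short constant flanks should reject the read, not
    distort the fidelity estimate.
    """

    template: str
    junction: int
    anchor5: str
    anchor3: str
    k: int = 3
    mode: str = FORWARD

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", to_dna(self.template))
        object.__setattr__(self, "anchor5", to_dna(self.anchor5))
        object.__setattr__(self, "anchor3", to_dna(self.anchor3))
        if self.k < 1:
            raise ValueError("substrate length k must be >= 1")
        if not self.anchor5 or not self.anchor3:
            raise ValueError("anchors must be nonempty")
        if not 1 <= self.junction <= len(self.template) - self.k + 1:
            raise ValueError("junction + k exceeds template")
        if self.mode not in (FORWARD, REVERSE):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def encoded(self) -> str:
        """Template-encoded k-mer at the junction (template 5'->3')."""
        return self.template[self.junction - 1 : self.junction - 1 + self.k]

    @property
    def expected_product(self) -> str:
        """The correctly incorporated k-mer as it appears in the product read
        (5'->3'): the reverse complement of the encoded template bases."""
        return revcomp(self.encoded)

    def substrate_kmer(self, product_kmer: str) -> str:
        """Orient a product-read k-mer into substrate N1..Nk order."""
        return product_kmer if self.mode == FORWARD else product_kmer[::-1]

    @classmethod
    def from_toml(cls, path: Union[str, Path]) -> "FidelityDesign":
        import tomllib

        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        return cls(**cfg)


@dataclass(frozen=True)
class FidelityRecord:
    """One classified read: incorporated vs encoded k-mer, substrate order."""

    incorporated: str  # substrate orientation, N1..Nk
    encoded: str  # expected substrate k-mer, N1..Nk
    matches: tuple[bool, ...]
    mode: str

    @property
    def k(self) -> int:
        return len(self.incorporated)


def classify_read(
    read: str, design: FidelityDesign
) -> Union[FidelityRecord, FidelityReject]:
    """Classify an extension-product read against the design.

    The k bases between the exact anchor matches are extracted, oriented
    into substrate order and compared to the expected substrate k-mer.
    """
    read = to_dna(read)
    i5 = read.find(design.anchor5)
    if i5 < 0:
        return FidelityReject(FidelityRejectReason.ANCHOR_MISSING)
    start = i5 + len(design.anchor5)
    i3 = read.find(design.anchor3, start)
    if i3 < 0:
        return FidelityReject(FidelityRejectReason.ANCHOR_MISSING)
    extracted = read[start:i3]
    if len(extracted) != design.k:
        return FidelityReject(FidelityRejectReason.WRONG_LENGTH)
    if set(extracted) - _DNA:
        return FidelityReject(FidelityRejectReason.AMBIGUOUS_BASE)
    incorporated = design.substrate_kmer(extracted)
    encoded = design.substrate_kmer(design.expected_product)
    matches = tuple(a == b for a, b in zip(incorporated, encoded))
    return FidelityRecord(incorporated, encoded, matches, design.mode)


# ---------------------------------------------------------------------------
# the model


class FidelityModel:
    """Per-position fidelity estimation from classified FidelitySeq reads."""

    def __init__(self, records: Sequence[FidelityRecord]):
        self.records = list(records)
        self.reject_reasons: Counter = Counter()

    @classmethod
    def from_reads(
        cls, reads: Iterable[str], design: FidelityDesign
    ) -> "FidelityModel":
        records = []
        rejects: Counter = Counter()
        for read in reads:
            result = classify_read(read, design)
            if isinstance(result, FidelityReject):
                rejects[result.reason.value] += 1
            else:
                records.append(result)
        model = cls(records)
        model.reject_reasons = rejects
        return model

    def fit(self, ci_alpha: float = 0.05) -> "FidelityResults":
        if not self.records:
            raise ValueError("no classified records")
        k = self.records[0].k
        n = len(self.records)
        n_correct = np.zeros(k, dtype=np.int64)
        for rec in self.records:
            for p, ok in enumerate(rec.matches):
                n_correct[p] += ok
        rows = []
        for p in range(k):
            lo, hi = proportion_confint(int(n_correct[p]), n, alpha=ci_alpha, method="wilson")
            rows.append(
                {
                    "position": p + 1,
                    "n": n,
                    "n_correct": int(n_correct[p]),
                    "fraction_correct": n_correct[p] / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        table = pd.DataFrame(rows).set_index("position")
        return FidelityResults(
            table, n_records=n, mode=self.records[0].mode, reject_reasons=dict(self.reject_reasons)
        )


def fidelity_per_position(records: Sequence[FidelityRecord]) -> "FidelityResults":
    """Per-position fraction correct with Wilson 95% CI (one-shot)."""
    return FidelityModel(records).fit()


class FidelityResults:
    """Per-position fidelity table plus the per-nucleotide aggregate."""

    def __init__(
        self,
        per_position: pd.DataFrame,
        n_records: int,
        mode: str,
        reject_reasons: Optional[dict] = None,
    ):
        self.per_position = per_position
        self.n_records = n_records
        self.mode = mode
        self.reject_reasons = reject_reasons or {}

    def per_nucleotide_fidelity(self, geometric: bool = False) -> float:
        """Aggregate fidelity across substrate positions.

        Arithmetic mean of the per-position fractions by default;
        geometric mean on request.
        """
        fr = self.per_position["fraction_correct"].to_numpy()
        if geometric:
            return float(np.exp(np.mean(np.log(fr))))
        return float(fr.mean())

    def summary(self) -> str:
        lines = [
            f"FidelitySeq per-position fidelity ({self.mode})",
            "=" * 54,
            f"reads classified:   {self.n_records}",
            f"reads rejected:     {sum(self.reject_reasons.values())} {self.reject_reasons}",
        ]
        for pos, row in self.per_position.iterrows():
            lines.append(
                f"  N{pos}: {row['fraction_correct']*100:6.2f}%  "
                f"[{row['ci_low']*100:.2f}, {row['ci_high']*100:.2f}] (Wilson 95%)"
            )
        lines.append(f"per-nucleotide fidelity: {self.per_nucleotide_fidelity()*100:.2f}%")
        return "\n".join(lines)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            self.per_position.to_csv(fh, sep="\t")
            fh.write(
                f"# per_nucleotide_fidelity\t{self.per_nucleotide_fidelity():.6f}"
                f"\t(mode={self.mode}, n={self.n_records})\n"
            )

    def plot_per_position(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tbl = self.per_position
        ax.errorbar(
            tbl.index,
            tbl["fraction_correct"],
            yerr=[tbl["fraction_correct"] - tbl["ci_low"], tbl["ci_high"] - tbl["fraction_correct"]],
            fmt="o",
        )
        ax.set_xlabel("substrate position (N1..Nk, 5'->3')")
        ax.set_ylabel("fraction correct")
        ax.set_ylim(0, 1.02)
        return ax


# ---------------------------------------------------------------------------
# competition fractions and composition bias


def competition_fraction(
    replicate_counts: Sequence[tuple[int, int]]
) -> tuple[float, float, list[float]]:
    """Fraction of correct substrate incorporation across experiment replicates.

    ``replicate_counts`` holds (correct, incorrect) per replicate.  Returns
    (mean, SD, per-replicate fractions); replicates with zero total reads
    are excluded with a warning.  SD uses ddof=1 (0.0 for one replicate).
    """
    fractions = []
    for correct, incorrect in replicate_counts:
        total = correct + incorrect
        if total == 0:
            import logging

            logging.getLogger(__name__).warning("replicate with zero total excluded")
            continue
        fractions.append(correct / total)
    if not fractions:
        raise ValueError("no replicate with nonzero total")
    mean = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if len(fractions) >= 2 else 0.0
    return mean, sd, fractions


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in "ACGT"]
    return kmers


def composition_bias(
    records: Sequence[FidelityRecord], expected_model: str = "uniform"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Incorporated k-mer composition against an expected model.

    Returns (kmer_table, au_trend): per-k-mer log2(observed/expected) with
    a -inf sentinel for unobserved k-mers, and the mean log2 ratio as a
    function of A+U content (0..k; classes with no observed k-mer are
    omitted).  ``template_weighted`` expects each record's encoded k-mer
    to be incorporated correctly (so the expected distribution follows the
    encoded k-mer spectrum); ``uniform`` expects all 4^k equally.
    """
    if not records:
        raise ValueError("no records")
    k = records[0].k
    n = len(records)
    kmers = _all_kmers(k)
    observed = Counter(rec.incorporated for rec in records)
    if expected_model == "uniform":
        expected = {km: n / 4**k for km in kmers}
    elif expected_model == "template_weighted":
        enc = Counter(rec.encoded for rec in records)
        expected = {km: enc.get(km, 0) for km in kmers}
    else:
        raise ValueError(f"unknown expected model {expected_model!r}")
    rows = []
    for km in kmers:
        obs = observed.get(km, 0)
        exp = expected[km]
        if obs == 0:
            ratio = -math.inf
        elif exp == 0:
            ratio = math.inf
        else:
            ratio = math.log2(obs / exp)
        rows.append(
            {
                "kmer": km.replace("T", "U"),
                "observed": obs,
                "expected": exp,
                "log2_ratio": ratio,
                "au_content": sum(b in "AT" for b in km),
            }
        )
    table = pd.DataFrame(rows).set_index("kmer")
    finite = table[np.isfinite(table["log2_ratio"])]
    trend = (
        finite.groupby("au_content")["log2_ratio"].agg(["mean", "count"]).reset_index()
    )
    trend.columns = ["au_content", "mean_log2_ratio", "n_kmers"]
    return table, trend
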