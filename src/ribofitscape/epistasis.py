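"""Pairwise epistasis of double mutants and its structural context.

Epistasis is defined additively in log-fitness space,

    epsilon = f_ab - f_a - f_b,

the standard multiplicative null given that fitness is already a log
enrichment.  Each double's SE propagates the replicate SEs of its three
constituent fitness values; significance uses a Student-t reference with
Welch-Satterthwaite degrees of freedom (with triplicate data the variance
estimates are too coarse for a normal reference to be calibrated) and
Benjamini-Hochberg FDR control across all tested pairs.

Pairs of mutated positions are classified against an annotated secondary
structure: a mutant combination at an annotated base pair is WC_pair if
the mutant bases are Watson-Crick complementary, wobble_pair if they form
G·U, pair_disrupting otherwise; positions that are not an annotated pair
are unpaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_calling import Genotype, Mutation, Reference, to_dna

logger = logging.getLogger(__name__)

WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})

PAIR_CLASSES = ("WC_pair", "wobble_pair", "pair_disrupting", "unpaired")

_OPENERS = "([{<"
_CLOSERS = ")]}>"


def classify_bases(base_i: str, base_j: str) -> str:
    """Classify a base combination: WC_pair, wobble_pair or pair_disrupting."""
    key = (to_dna(base_i), to_dna(base_j))
    if key in WC_PAIRS:
        return "WC_pair"
    if key in WOBBLE_PAIRS:
        return "wobble_pair"
    return "pair_disrupting"


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    """Parse a dot-bracket string into 1-based (i, j) pairs, i < j.

    Pseudoknot layers written with (), [], {}, <> and upper/lower-case
    letter pairs (Aa, Bb, ...) are all supported.
    """
    stacks: dict[str, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db, start=1):
        if ch in "._,:-":
            continue
        if ch in _OPENERS:
            stacks.setdefault(ch, []).append(idx)
        elif ch in _CLOSERS:
            opener = _OPENERS[_CLOSERS.index(ch)]
            stack = stacks.get(opener)
            if not stack:
                raise ValueError(f"unbalanced {ch!r} at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch.isalpha() and ch.isupper():
            stacks.setdefault(ch, []).append(idx)
        elif ch.isalpha() and ch.islower():
            stack = stacks.get(ch.upper())
            if not stack:
                raise ValueError(f"unbalanced {ch!r} at position {idx}")
            pairs.append((stack.pop(), idx))
        else:
            raise ValueError(f"unrecognized structure character {ch!r}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unclosed {opener!r} at positions {stack}")
    return sorted(pairs)


PosKey = tuple[str, int]  # (subunit_id, 1-based position)


@dataclass
class SecondaryStructure:
    """Annotated base pairs, intra- and (optionally) inter-subunit.

    ``pairs`` holds ((sub_i, pos_i), (sub_j, pos_j), tag) with tag in
    {intra-helix, kissing-loop, noncanonical}.  No position may take part
    in more than one pair.
    """

    pairs: list[tuple[PosKey, PosKey, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[PosKey] = set()
        for i, j, _tag in self.pairs:
            for key in (i, j):
                if key in seen:
                    raise ValueError(f"position {key} participates in more than one pair")
                seen.add(key)
        self._partner: dict[PosKey, tuple[PosKey, str]] = {}
        for i, j, tag in self.pairs:
            self._partner[i] = (j, tag)
            self._partner[j] = (i, tag)

    @classmethod
    def from_dot_bracket(
        cls, subunit_id: str, db: str, tag: str = "intra-helix"
    ) -> "SecondaryStructure":
        pairs = [
            ((subunit_id, i), (subunit_id, j), tag) for i, j in parse_dot_bracket(db)
        ]
        return cls(pairs)

    @classmethod
    def from_files(
        cls,
        dot_brackets: dict[str, str],
        extra_pairs_tsv: Optional[Union[str, Path]] = None,
    ) -> "SecondaryStructure":
        """Build from per-subunit dot-bracket strings plus an optional TSV of
        extra pairs (columns subunit_i, pos_i, subunit_j, pos_j, tag)."""
        pairs: list[tuple[PosKey, PosKey, str]] = []
        for sub, db in dot_brackets.items():
            pairs.extend(((sub, i), (sub, j), "intra-helix") for i, j in parse_dot_bracket(db))
        if extra_pairs_tsv is not None:
            extra = pd.read_csv(extra_pairs_tsv, sep="\t")
            for _, row in extra.iterrows():
                pairs.append(
                    (
                        (str(row["subunit_i"]), int(row["pos_i"])),
                        (str(row["subunit_j"]), int(row["pos_j"])),
                        str(row.get("tag", "noncanonical")),
                    )
                )
        return cls(pairs)

    def partner(self, subunit_id: str, position: int) -> Optional[PosKey]:
        hit = self._partner.get((subunit_id, position))
        return hit[0] if hit else None

    def is_pair(self, key_i: PosKey, key_j: PosKey) -> bool:
        hit = self._partner.get(key_i)
        return hit is not None and hit[0] == key_j


def classify_pair(
    genotype: Genotype, structure: SecondaryStructure, ref: Reference
) -> str:
    """Pair-structure class of a substitution double mutant."""
    if genotype.hamming != 2:
        raise ValueError("classify_pair expects a double mutant")
    m1, m2 = genotype.mutations
    if m1.is_deletion or m2.is_deletion:
        raise ValueError("pair classification is undefined for deletions")
    sub = genotype.subunit_id
    if structure.is_pair((sub, m1.position), (sub, m2.position)):
        return classify_bases(m1.alt, m2.alt)
    return "unpaired"


def classify_single_partner_state(
    mutation: Mutation, subunit_id: str, structure: SecondaryStructure, ref: Reference
) -> str:
    """Class of the base pair formed by a single mutation with the wild-type
    partner base, or 'unpaired' if the position is not annotated as paired."""
    partner = structure.partner(subunit_id, mutation.position)
    if partner is None or mutation.is_deletion:
        return "unpaired"
    partner_base = ref.base(partner[1]) if partner[0] == subunit_id else None
    if partner_base is None:
        return "unpaired"
    return classify_bases(mutation.alt, partner_base)


# ---------------------------------------------------------------------------
# the model


class EpistasisModel:
    """Pairwise epistasis over a fitted fitness landscape.

    Built from :class:`~ribofitscape.fitness.FitnessResults`; optionally
    annotates each double with its pair-structure class (``structure``)
    and 3D residue distance (``distances``, a
    :class:`~ribofitscape.structure_map.DistanceMatrix`).
    """

    def __init__(self, fitness_results, structure: Optional[SecondaryStructure] = None,
                 distances=None, exclude_deletions: bool = True):
        self.fitness_results = fitness_results
        self.structure = structure
        self.distances = distances
        self.exclude_deletions = exclude_deletions

    def fit(self, fdr_level: float = 0.05) -> "EpistasisResults":
        res = self.fitness_results
        table = res.table
        ct = res.count_table
        if ct is None:
            from .genotype_calling import parse_genotype_label

            genotypes = {
                lbl: parse_genotype_label(lbl, str(table["subunit"].iloc[0]))
                for lbl in table.index
            }
        else:
            genotypes = ct.genotypes
        ref = None
        mean = table["mean_fitness"]
        se = table["se_fitness"]
        n_obs = table["n_replicates_observed"]
        single_by_mut = {
            g.mutations[0].label: lbl
            for lbl, g in genotypes.items()
            if g.hamming == 1
        }
        rows = []
        n_skipped = 0
        for lbl, g in genotypes.items():
            if g.hamming != 2:
                continue
            m1, m2 = g.mutations
            if self.exclude_deletions and (m1.is_deletion or m2.is_deletion):
                continue
            la = single_by_mut.get(m1.label)
            lb = single_by_mut.get(m2.label)
            if la is None or lb is None:
                n_skipped += 1
                continue
            f_ab, f_a, f_b = mean[lbl], mean[la], mean[lb]
            if not (np.isfinite(f_ab) and np.isfinite(f_a) and np.isfinite(f_b)):
                n_skipped += 1
                continue
            eps = f_ab - f_a - f_b
            ses = np.array([se[lbl], se[la], se[lb]], dtype=float)
            dfs = np.array([n_obs[lbl], n_obs[la], n_obs[lb]], dtype=float) - 1
            if np.isfinite(ses).all() and (dfs > 0).all():
                se_eps = float(np.sqrt((ses**2).sum()))
                # Welch-Satterthwaite effective df for the variance sum
                df_eff = float((ses**2).sum() ** 2 / ((ses**4) / dfs).sum())
            else:
                se_eps, df_eff = float("nan"), float("nan")
            row = {
                "genotype_label": lbl,
                "label_a": la,
                "label_b": lb,
                "subunit": g.subunit_id,
                "pos_i": m1.position,
                "pos_j": m2.position,
                "f_ab": f_ab,
                "f_a": f_a,
                "f_b": f_b,
                "epsilon": eps,
                "se_epsilon": se_eps,
                "df": df_eff,
            }
            if self.structure is not None:
                row["pair_class"] = classify_pair(g, self.structure, ref)
            if self.distances is not None:
                row["distance_A"] = self.distances.get(
                    (g.subunit_id, m1.position), (g.subunit_id, m2.position)
                )
            rows.append(row)
        records = pd.DataFrame(rows)
        if len(records):
            records = records.set_index("genotype_label")
            records = epistasis_significance(records, fdr_level=fdr_level, strict=False)
        return EpistasisResults(records, fdr_level=fdr_level, n_skipped=n_skipped)


def compute_epistasis(fitness_results, **kwargs) -> "EpistasisResults":
    """One-shot epistasis computation (see :class:`EpistasisModel`)."""
    fdr_level = kwargs.pop("fdr_level", 0.05)
    return EpistasisModel(fitness_results, **kwargs).fit(fdr_level=fdr_level)


def epistasis_significance(
    records: pd.DataFrame, fdr_level: float = 0.05, strict: bool = True
) -> pd.DataFrame:
    """Attach p- and BH q-values to epistasis records.

    t = epsilon / se_epsilon against a Student-t reference with the
    record's Welch-Satterthwaite df; BH correction across all records with
    a defined SE.
    """
    records = records.copy()
    testable = records["se_epsilon"].notna() & (records["se_epsilon"] > 0)
    if strict and not testable.any():
        raise ValueError("no record has a defined se_epsilon; need >= 2 replicates")
    records["p_value"] = np.nan
    records["q_value"] = np.nan
    records["significant"] = False
    if testable.any():
        sub = records.loc[testable]
        tstat = sub["epsilon"] / sub["se_epsilon"]
        p = 2.0 * stats.t.sf(np.abs(tstat), df=sub["df"])
        reject, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
        records.loc[testable, "p_value"] = p
        records.loc[testable, "q_value"] = q
        records.loc[testable, "significant"] = reject
    return records


class EpistasisResults:
    """Epistasis records with significance and structural annotation."""

    def __init__(self, records: pd.DataFrame, fdr_level: float, n_skipped: int = 0):
        self.records = records
        self.fdr_level = fdr_level
        self.n_skipped = n_skipped

    @property
    def mean_epsilon(self) -> float:
        return float(self.records["epsilon"].mean())

    @property
    def significant_fraction(self) -> float:
        tested = self.records["q_value"].notna()
        if not tested.any():
            return float("nan")
        return float(self.records.loc[tested, "significant"].mean())

    def mean_epsilon_by_class(self) -> pd.Series:
        if "pair_class" not in self.records:
            raise ValueError("records carry no pair_class; fit with a structure")
        return self.records.groupby("pair_class")["epsilon"].mean()

    def vs_distance(self, bin_edges: Iterable[float]) -> pd.DataFrame:
        return epistasis_vs_distance(self.records, bin_edges)

    def vs_single_fitness(self, bin_edges: Iterable[float]) -> pd.DataFrame:
        return epistasis_vs_single_fitness(self.records, bin_edges)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.records.to_csv(path, sep="\t")

    def summary(self) -> str:
        rec = self.records
        lines = [
            "Pairwise epistasis (epsilon = f_ab - f_a - f_b)",
            "=" * 54,
            f"doubles analyzed:     {len(rec)} (skipped for missing singles: {self.n_skipped})",
            f"mean epsilon:         {self.mean_epsilon:+.4f}",
            f"FDR level:            {self.fdr_level}",
            f"significant fraction: {self.significant_fraction:.3f}",
        ]
        if "pair_class" in rec:
            for cls_name, val in self.mean_epsilon_by_class().items():
                n = int((rec["pair_class"] == cls_name).sum())
                lines.append(f"  {cls_name:<16s} n={n:>6d}  mean eps = {val:+.4f}")
        return "\n".join(lines)

    def plot_vs_distance(self, bin_edges: Iterable[float], ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        binned = self.vs_distance(bin_edges)
        centers = [(lo + hi) / 2 for lo, hi in zip(binned["bin_lo"], binned["bin_hi"])]
        ax.plot(centers, binned["mean_abs_epsilon"], "o-")
        ax.set_xlabel("residue distance (Å)")
        ax.set_ylabel("mean |epsilon|")
        return ax


def epistasis_vs_distance(
    records: pd.DataFrame, bin_edges: Iterable[float]
) -> pd.DataFrame:
    """Bin epistasis records by 3D residue distance (right-open bins).

    Records without a defined distance are skipped.  Empty bins are kept
    with n = 0.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if "distance_A" not in records:
        raise ValueError("records carry no distance_A; fit with a distance matrix")
    rec = records[records["distance_A"].notna()]
    idx = np.digitize(rec["distance_A"], edges) - 1  # bin k covers [edges[k], edges[k+1])
    rows = []
    for k in range(len(edges) - 1):
        sel = rec[idx == k]
        rows.append(
            {
                "bin_lo": edges[k],
                "bin_hi": edges[k + 1],
                "n": len(sel),
                "mean_abs_epsilon": float(sel["epsilon"].abs().mean()) if len(sel) else float("nan"),
                "mean_epsilon": float(sel["epsilon"].mean()) if len(sel) else float("nan"),
                "significant_fraction": float(sel["significant"].mean())
                if len(sel) and "significant" in sel
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def epistasis_vs_single_fitness(
    records: pd.DataFrame, bin_edges: Iterable[float]
) -> pd.DataFrame:
    """Mean epsilon binned by the fitness of the 'first' single mutation.

    Both orderings of each double are emitted (a as first, then b as
    first), so every double contributes two observations.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if len(records) == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "n", "mean_epsilon"])
    stacked = pd.DataFrame(
        {
            "f_first": pd.concat([records["f_a"], records["f_b"]], ignore_index=True),
            "epsilon": pd.concat([records["epsilon"], records["epsilon"]], ignore_index=True),
        }
    )
    idx = np.digitize(stacked["f_first"], edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        sel = stacked[idx == k]
        rows.append(
            {
                "bin_lo": edges[k],
                "bin_hi": edges[k + 1],
                "n": len(sel),
                "mean_epsilon": float(sel["epsilon"].mean()) if len(sel) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
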