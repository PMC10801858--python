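"""Per-genotype fitness as log-enrichment relative to wild type.

Fitness of genotype v in replicate r is

    f_vr = log[ ((c_post_v + a) / (c_post_wt + a)) / ((c_pre_v + a) / (c_pre_wt + a)) ]

with pseudocount a (default 0.5, the half-count correction that removes the
first-order concavity bias of the log).  The wild type scores exactly 0 in
every replicate, and the statistic is invariant to uniform scaling of the
sequencing depth within any (replicate, phase).

The natural log is the default; any base can be requested.  Replicates are
aggregated by unweighted mean with the SE taken from replicate scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_calling import CountTable, Reference, parse_genotype_label


class EnrichmentModel:
    """Log-enrichment fitness model over a pre/post selection count table.

    Parameters
    ----------
    table:
        Filtered count table; the wild type must have nonzero pre and post
        counts in every replicate (or a positive pseudocount).
    pseudocount:
        Symmetric additive pseudocount a >= 0.  With a = 0, genotypes with
        zero post-selection counts are censored at -inf.
    log_base:
        Base of the log transform (natural log by default).
    pooled:
        If True, counts are summed over replicates before the ratio is
        formed (single fitness value, no SE) instead of the default
        per-replicate-then-average mode.
    """

    def __init__(
        self,
        table: CountTable,
        pseudocount: float = 0.5,
        log_base: float = math.e,
        pooled: bool = False,
    ):
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.table = table
        self.pseudocount = pseudocount
        self.log_base = log_base
        self.pooled = pooled

    @classmethod
    def from_tsv(cls, path: Union[str, Path], **kwargs) -> "EnrichmentModel":
        return cls(CountTable.from_tsv(path), **kwargs)

    def fit(self) -> "FitnessResults":
        tbl = self.table
        a = self.pseudocount
        if "wt" not in tbl.counts.index:
            raise ValueError("wild type absent from count table")
        counts = tbl.counts
        if self.pooled:
            counts = counts.T.groupby(level="phase").sum().T
            counts.columns = pd.MultiIndex.from_product(
                [["pooled"], counts.columns], names=["replicate", "phase"]
            )
        reps = list(counts.columns.levels[0])
        pre = counts.xs("pre", axis=1, level="phase").astype(float)
        post = counts.xs("post", axis=1, level="phase").astype(float)
        wt_pre = pre.loc["wt"]
        wt_post = post.loc["wt"]
        if a == 0 and ((wt_pre == 0).any() or (wt_post == 0).any()):
            raise ValueError("wild type has zero counts and pseudocount is 0")
        with np.errstate(divide="ignore"):
            log_ratio = np.log((post + a).div(wt_post + a, axis=1)) - np.log(
                (pre + a).div(wt_pre + a, axis=1)
            )
        fitness = log_ratio / math.log(self.log_base)
        censored = (post == 0) & (a == 0)
        observed = (pre > 0) & ~censored
        fit_obs = fitness.where(observed)
        n_obs = observed.sum(axis=1)
        mean = fit_obs.mean(axis=1)
        sd = fit_obs.std(axis=1, ddof=1)
        se = sd / np.sqrt(n_obs.where(n_obs > 0))
        se = se.where(n_obs >= 2)

        out = pd.DataFrame(index=counts.index)
        out["subunit"] = tbl.subunit_id
        out["hamming"] = tbl.hamming() if not self.pooled else pd.Series(
            {lbl: g.hamming for lbl, g in tbl.genotypes.items()}
        ).reindex(counts.index)
        for rep in reps:
            out[f"fitness_{rep}"] = fitness[rep]
            out[f"censored_{rep}"] = censored[rep]
        out["mean_fitness"] = mean
        out["se_fitness"] = se
        out["n_replicates_observed"] = n_obs
        return FitnessResults(out, tbl, replicates=reps, pseudocount=a, log_base=self.log_base)


def compute_fitness(
    table: CountTable, pseudocount: float = 0.5, **kwargs
) -> "FitnessResults":
    """One-shot fitness computation (see :class:`EnrichmentModel`)."""
    return EnrichmentModel(table, pseudocount=pseudocount, **kwargs).fit()


class FitnessResults:
    """Fitted per-genotype fitness values with replicate aggregation.

    ``table`` holds one row per genotype: per-replicate fitness and
    censoring flags, mean, SE, and the number of replicates observed.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        count_table: Optional[CountTable],
        replicates: list[str],
        pseudocount: float,
        log_base: float,
    ):
        self.table = table
        self.count_table = count_table
        self.replicates = replicates
        self.pseudocount = pseudocount
        self.log_base = log_base

    # -- accessors

    def fitness(self, label: str) -> float:
        return float(self.table.loc[label, "mean_fitness"])

    @property
    def mean_fitness(self) -> pd.Series:
        return self.table["mean_fitness"]

    @property
    def se_fitness(self) -> pd.Series:
        return self.table["se_fitness"]

    def replicate_fitness(self, rep: str) -> pd.Series:
        return self.table[f"fitness_{rep}"]

    # -- landscape summaries

    def replicate_correlation(
        self, rep1: str, rep2: str, max_hamming: Optional[int] = None
    ) -> float:
        """Pearson r between two replicates over shared, uncensored genotypes."""
        return replicate_correlation(
            self.replicate_fitness(rep1),
            self.replicate_fitness(rep2),
            max_hamming=max_hamming,
            hamming=self.table["hamming"],
        )

    def by_hamming(self) -> pd.DataFrame:
        """Mean fitness and genotype count per Hamming-distance class."""
        return fitness_by_hamming(self)

    def position_map(self, ref: Reference) -> pd.DataFrame:
        """Per-position mean fitness over observed substitution singles."""
        return per_position_mean_fitness(self, ref)

    # -- I/O and presentation

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, sep="\t", index_label="genotype_label")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "FitnessResults":
        df = pd.read_csv(path, sep="\t", index_col="genotype_label")
        reps = [c[len("fitness_"):] for c in df.columns if c.startswith("fitness_")]
        return cls(df, None, replicates=reps, pseudocount=float("nan"), log_base=math.e)

    def summary(self) -> str:
        df = self.table
        lines = [
            "Log-enrichment fitness (relative to wild type)",
            "=" * 54,
            f"genotypes:            {len(df)}",
            f"replicates:           {len(self.replicates)} ({', '.join(self.replicates)})",
            f"pseudocount:          {self.pseudocount}",
            f"log base:             {'e' if self.log_base == math.e else self.log_base}",
            f"mean fitness:         {df['mean_fitness'].mean():.4f}",
            f"median fitness:       {df['mean_fitness'].median():.4f}",
        ]
        by_h = self.by_hamming()
        for h, row in by_h.iterrows():
            lines.append(f"  Hamming {h}: n={int(row['n']):>7d}  mean f = {row['mean_fitness']:+.4f}")
        if len(self.replicates) >= 2:
            r12 = self.replicate_correlation(self.replicates[0], self.replicates[1])
            lines.append(f"replicate correlation ({self.replicates[0]} vs {self.replicates[1]}): R = {r12:.3f}")
        return "\n".join(lines)

    def plot_by_hamming(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        by_h = self.by_hamming()
        ax.plot(by_h.index, by_h["mean_fitness"], "o-")
        ax.set_xlabel("Hamming distance from wt")
        ax.set_ylabel("mean fitness (log enrichment)")
        return ax

    def plot_replicates(self, rep1: str, rep2: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.replicate_fitness(rep1), self.replicate_fitness(rep2), ".", alpha=0.3)
        ax.set_xlabel(f"fitness {rep1}")
        ax.set_ylabel(f"fitness {rep2}")
        return ax


# ---------------------------------------------------------------------------
# free functions (operate on vectors / results)


def aggregate_replicates(values: np.ndarray) -> tuple[float, float, int]:
    """Mean, SE and n over observed (finite) replicate fitness values.

    Censored (-inf) and missing replicates are excluded.  SE is undefined
    (nan) for fewer than two observations.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return mean, se, n


def replicate_correlation(
    f1: pd.Series,
    f2: pd.Series,
    max_hamming: Optional[int] = None,
    hamming: Optional[pd.Series] = None,
) -> float:
    """Pearson correlation between two per-replicate fitness vectors.

    Only genotypes finite in both replicates count; with ``max_hamming``
    the comparison is restricted to low-order mutants (as done when
    reporting landscape reproducibility for singles and doubles only).
    """
    df = pd.DataFrame({"f1": f1, "f2": f2})
    if max_hamming is not None:
        if hamming is None:
            raise ValueError("max_hamming requires a hamming vector")
        df = df[hamming.reindex(df.index) <= max_hamming]
    df = df.replace([np.inf, -np.inf], np.nan).dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 shared genotypes")
    r, _ = stats.pearsonr(df["f1"], df["f2"])
    return float(r)


def fitness_by_hamming(results: FitnessResults) -> pd.DataFrame:
    """Mean of mean_fitness per Hamming class; empty classes omitted."""
    df = results.table.replace([np.inf, -np.inf], np.nan)
    grouped = df.groupby("hamming")["mean_fitness"].agg(["mean", "count"])
    grouped.columns = ["mean_fitness", "n"]
    return grouped[grouped["n"] > 0]


def per_position_mean_fitness(results: FitnessResults, ref: Reference) -> pd.DataFrame:
    """Mean fitness of observed substitution single mutants per position.

    Deletion singles are reported in a separate column and excluded from
    the substitution mean.  Positions with no observed singles carry NaN
    (missing, not zero).
    """
    if results.count_table is not None:
        genotypes = results.count_table.genotypes
    else:
        genotypes = {
            lbl: parse_genotype_label(lbl, ref.subunit_id) for lbl in results.table.index
        }
    sub_vals: dict[int, list[float]] = {}
    del_vals: dict[int, float] = {}
    for lbl, g in genotypes.items():
        if g.hamming != 1 or lbl not in results.table.index:
            continue
        m = g.mutations[0]
        f = float(results.table.loc[lbl, "mean_fitness"])
        if not math.isfinite(f):
            continue
        if m.is_deletion:
            del_vals[m.position] = f
        else:
            sub_vals.setdefault(m.position, []).append(f)
    rows = []
    for pos in range(1, ref.length + 1):
        subs = sub_vals.get(pos, [])
        rows.append(
            {
                "subunit": ref.subunit_id,
                "position": pos,
                "ref_base": ref.base(pos).translate(str.maketrans("T", "U")),
                "mean_fitness": float(np.mean(subs)) if subs else float("nan"),
                "n_obs": len(subs),
                "deletion_fitness": del_vals.get(pos, float("nan")),
            }
        )
    return pd.DataFrame(rows).set_index("position")
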