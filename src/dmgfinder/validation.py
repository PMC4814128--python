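"""Marker validation statistics against strain phenotypes.

A candidate marker gene is judged by how well its presence/absence across a
strain panel separates the phenotype classes: a 2x2 confusion table against
the binary ability (here: spoiler vs non-spoiler), a two-sided Fisher exact
test on that table, and Spearman's rank correlation against the ordinal
potential classes (NB < WB < MB < SB, encoded 0..3 by default; a strain is
a spoiler iff its class is MB or above).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RANK_ENCODING = {"NB": 0, "WB": 1, "MB": 2, "SB": 3}
SPOILER_MIN_RANK = 2  # MB and above = able to spoil


@dataclass
class PhenotypeTable:
    """strain -> binary ability and ordinal potential rank."""

    ability: dict[str, str]  # strain -> {"spoiler", "non_spoiler"}
    potential_rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for strain, label in self.ability.items():
            if label not in ("spoiler", "non_spoiler"):
                raise ValueError(
                    f"strain {strain!r}: ability must be spoiler/non_spoiler, "
                    f"got {label!r}"
                )

    @classmethod
    def from_ranks(
        cls,
        classes: dict[str, str],
        encoding: dict[str, int] | None = None,
        spoiler_min_rank: int = SPOILER_MIN_RANK,
    ) -> "PhenotypeTable":
        """Build from ordinal class labels; ability derives from the rank."""
        encoding = encoding or DEFAULT_RANK_ENCODING
        ranks = {s: encoding[c] for s, c in classes.items()}
        ability = {
            s: "spoiler" if r >= spoiler_min_rank else "non_spoiler"
            for s, r in ranks.items()
        }
        return cls(ability=ability, potential_rank=ranks)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"strain", "ability"}
        if not required <= set(df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        ability = dict(zip(df["strain"], df["ability"]))
        ranks = {}
        if "potential_rank" in df.columns:
            ranks = {s: int(r) for s, r in zip(df["strain"], df["potential_rank"])}
        return cls(ability=ability, potential_rank=ranks)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts for one marker.

    a: spoilers marker-positive; b: spoilers marker-negative (false
    negatives); c: non-spoilers marker-positive (false positives);
    d: non-spoilers marker-negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def correct_pct(self) -> float:
        return 100.0 * (self.a + self.d) / self.n


@dataclass
class MarkerStats:
    marker: str
    fisher_p: float
    spearman_rho: float | None
    spearman_significant: bool | None
    correct_pct: float
    false_positive: int
    false_negative: int


def fisher_exact_two_sided(t: ConfusionTable) -> float:
    """Two-sided Fisher exact probability of a 2x2 table.

    Sum of point hypergeometric probabilities over all tables with the same
    margins whose probability does not exceed the observed one (exact
    enumeration; no normal approximation).
    """
    if t.n == 0 or (t.a + t.b) == 0 or (t.c + t.d) == 0 \
            or (t.a + t.c) == 0 or (t.b + t.d) == 0:
        return 1.0
    return float(
        stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    )


def spearman_rho(x, y) -> tuple[float, bool]:
    """Spearman rank correlation with mid-rank ties and a two-sided
    t-approximation significance call at the 95% level.

    Returns (rho, significant). Raises on constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman rho is undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), bool(res.pvalue < 0.05)


def confusion_counts(
    presence: dict[str, int] | pd.Series, pheno: PhenotypeTable
) -> ConfusionTable:
    """Confusion table of one marker's presence calls against ability."""
    if isinstance(presence, pd.Series):
        presence = presence.to_dict()
    missing = sorted(set(presence) - set(pheno.ability))
    if missing:
        raise ValueError(f"strain(s) missing from phenotype table: {missing}")
    a = b = c = d = 0
    for strain, present in presence.items():
        spoiler = pheno.ability[strain] == "spoiler"
        if spoiler and present:
            a += 1
        elif spoiler:
            b += 1
        elif present:
            c += 1
        else:
            d += 1
    return ConfusionTable(a=a, b=b, c=c, d=d)


def evaluate_markers(
    matrix: pd.DataFrame, pheno: PhenotypeTable
) -> pd.DataFrame:
    """Per-marker statistics, sorted by descending Fisher P.

    ``matrix``: markers as rows, strains as columns, cells 0/1. Spearman is
    computed against the ordinal potential ranks when available; a
    non-significant rho renders as ``NS``.
    """
    if matrix.empty:
        raise ValueError("need at least one marker")
    if matrix.isna().any().any():
        raise ValueError("presence matrix must be complete (no missing cells)")
    rows = []
    for marker, presence in matrix.iterrows():
        t = confusion_counts(presence, pheno)
        p = fisher_exact_two_sided(t)
        rho: float | None = None
        sig: bool | None = None
        if pheno.potential_rank:
            ranks = [pheno.potential_rank[s] for s in matrix.columns]
            calls = [int(presence[s]) for s in matrix.columns]
            try:
                rho, sig = spearman_rho(calls, ranks)
            except ValueError:
                rho, sig = None, None
        rows.append(
            MarkerStats(
                marker=str(marker), fisher_p=p, spearman_rho=rho,
                spearman_significant=sig, correct_pct=t.correct_pct,
                false_positive=t.c, false_negative=t.b,
            )
        )
    df = pd.DataFrame(
        {
            "marker": [r.marker for r in rows],
            "fisher_p": [r.fisher_p for r in rows],
            "spearman_rho": [
                ("NS" if not r.spearman_significant else round(r.spearman_rho, 2))
                if r.spearman_rho is not None else "NA"
                for r in rows
            ],
            "correct_discrimination_pct": [r.correct_pct for r in rows],
            "false_positive": [r.false_positive for r in rows],
            "false_negative": [r.false_negative for r in rows],
        }
    )
    return df.sort_values(
        "fisher_p", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
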