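"""Cohort-level statistics on match tables.

Presence/absence, group-exclusive chimera sets, cross-cohort frequency
comparison with a direction-consistency flag, marker sensitivity /
specificity, and parental-gene chromosome enrichment (one-sided binomial
against the annotated gene background, Benjamini-Hochberg corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ChimeraCall, GeneModel, MatchTable, ValidationError


@dataclass
class PresenceMatrix:
    """Boolean samples x chimeras matrix: count >= threshold."""

    values: pd.DataFrame
    groups: pd.Series
    threshold: int

    @property
    def case_samples(self) -> list[str]:
        return list(self.values.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.values.index[self.groups == "control"])


@dataclass
class ExclusivityResult:
    """Partition of the chimera universe by group-restricted presence."""

    case_exclusive: set[str]
    control_exclusive: set[str]
    shared: set[str]
    absent: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, ids in (
            ("case_exclusive", self.case_exclusive),
            ("control_exclusive", self.control_exclusive),
            ("shared", self.shared),
            ("absent", self.absent),
        ):
            for cid in sorted(ids):
                rows.append({"chimera_id": cid, "exclusivity": label})
        return pd.DataFrame(rows, columns=["chimera_id", "exclusivity"])


@dataclass
class MarkerPerformance:
    """2x2 presence accounting for one marker chimera."""

    chimera_id: str
    n_cases: int
    n_controls: int
    true_positives: int
    false_negatives: int
    false_positives: int
    true_negatives: int

    def __post_init__(self) -> None:
        assert self.true_positives + self.false_negatives == self.n_cases
        assert self.false_positives + self.true_negatives == self.n_controls

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.n_cases

    @property
    def specificity(self) -> float:
        return self.true_negatives / self.n_controls

    @property
    def sensitivity_pct(self) -> float:
        return round_half_up(100 * self.sensitivity, 1)

    @property
    def specificity_pct(self) -> float:
        return round_half_up(100 * self.specificity, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chimera_id": self.chimera_id,
                    "n_cases": self.n_cases,
                    "n_controls": self.n_controls,
                    "true_positives": self.true_positives,
                    "false_negatives": self.false_negatives,
                    "false_positives": self.false_positives,
                    "true_negatives": self.true_negatives,
                    "sensitivity_pct": self.sensitivity_pct,
                    "specificity_pct": self.specificity_pct,
                }
            ]
        )


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (so 11/12 -> 91.7%)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def presence(match_table: MatchTable, threshold: int = 1) -> PresenceMatrix:
    """Binarize a match table: a chimera is present where count >= threshold."""
    if threshold < 1:
        raise ValidationError("presence threshold must be >= 1")
    return PresenceMatrix(
        values=match_table.counts >= threshold,
        groups=match_table.groups,
        threshold=threshold,
    )


def exclusivity(pm: PresenceMatrix) -> ExclusivityResult:
    """Partition chimeras into case-exclusive / control-exclusive / shared / absent."""
    cases, controls = pm.case_samples, pm.control_samples
    if not cases or not controls:
        raise ValidationError("exclusivity requires both case and control samples")
    in_case = pm.values.loc[cases].any(axis=0)
    in_control = pm.values.loc[controls].any(axis=0)
    ids = pm.values.columns
    return ExclusivityResult(
        case_exclusive=set(ids[in_case & ~in_control]),
        control_exclusive=set(ids[~in_case & in_control]),
        shared=set(ids[in_case & in_control]),
        absent=set(ids[~in_case & ~in_control]),
    )


def frequency_comparison(
    match_tables: dict[str, MatchTable],
    threshold: int = 1,
) -> pd.DataFrame:
    """Long-format per-(database, chimera, group) totals with consistency flags.

    ``direction_consistent`` is true for a chimera when the sign of the
    case-minus-control total count agrees across every database in which it
    is non-zero somewhere. Chimeras missing from a table are recorded as
    zero and flagged ``missing``.
    """
    all_ids: list[str] = []
    for table in match_tables.values():
        for cid in table.chimera_ids:
            if cid not in all_ids:
                all_ids.append(cid)
    rows = []
    directions: dict[str, list[int]] = {cid: [] for cid in all_ids}
    for db, table in match_tables.items():
        pm = presence(table, threshold)
        for cid in all_ids:
            missing = cid not in table.counts.columns
            for group in ("case", "control"):
                samples = table.counts.index[table.groups == group]
                total = 0 if missing else int(table.counts.loc[samples, cid].sum())
                n_pos = 0 if missing else int(pm.values.loc[samples, cid].sum())
                rows.append(
                    {
                        "database": db,
                        "chimera_id": cid,
                        "group": group,
                        "total_match_count": total,
                        "n_positive_samples": n_pos,
                        "missing": missing,
                    }
                )
            if not missing:
                case_total = rows[-2]["total_match_count"]
                control_total = rows[-1]["total_match_count"]
                directions[cid].append(int(np.sign(case_total - control_total)))
    consistent = {
        cid: len({d for d in dirs if d != 0}) <= 1 and any(d != 0 for d in dirs)
        for cid, dirs in directions.items()
    }
    df = pd.DataFrame(rows)
    df["direction_consistent"] = df["chimera_id"].map(consistent)
    return df


def marker_performance(pm: PresenceMatrix, chimera_id: str) -> MarkerPerformance:
    """Sensitivity/specificity of one chimera as a case marker."""
    if chimera_id not in pm.values.columns:
        raise ValidationError(f"unknown chimera id {chimera_id!r}")
    cases, controls = pm.case_samples, pm.control_samples
    if not cases or not controls:
        raise ValidationError("marker performance requires both groups")
    col = pm.values[chimera_id]
    tp = int(col.loc[cases].sum())
    fp = int(col.loc[controls].sum())
    return MarkerPerformance(
        chimera_id=chimera_id,
        n_cases=len(cases),
        n_controls=len(controls),
        true_positives=tp,
        false_negatives=len(cases) - tp,
        false_positives=fp,
        true_negatives=len(controls) - fp,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def chromosome_enrichment(
    calls: Iterable[ChimeraCall],
    annotation: Sequence[GeneModel],
    side: str = "both",
) -> pd.DataFrame:
    """Per-chromosome enrichment of parental genes among annotated genes.

    One-sided binomial tail P(X >= observed) with X ~ Binomial(n parental
    genes, chromosome's share of annotated genes); parental genes are
    deduplicated by symbol per side.
    """
    if side not in ("5prime", "3prime", "both"):
        raise ValidationError(f"side must be 5prime, 3prime or both, got {side!r}")
    gene_chrom = {g.symbol: g.chrom for g in annotation}
    parental: set[tuple[str, str]] = set()
    for call in calls:
        if side in ("5prime", "both"):
            parental.add(("5prime", call.gene5))
        if side in ("3prime", "both"):
            parental.add(("3prime", call.gene3))
    observed: dict[str, int] = {}
    for _, symbol in parental:
        chrom = gene_chrom.get(symbol)
        if chrom is None:
            raise ValidationError(f"parental gene {symbol} has no annotated chromosome")
        observed[chrom] = observed.get(chrom, 0) + 1
    background = pd.Series([g.chrom for g in annotation]).value_counts()
    n_total = int(background.sum())
    n_parental = len(parental)
    rows = []
    for chrom in sorted(background.index):
        bg = int(background[chrom])
        obs = observed.get(chrom, 0)
        prop = bg / n_total
        pval = float(stats.binom.sf(obs - 1, n_parental, prop)) if n_parental else 1.0
        rows.append(
            {
                "chrom": chrom,
                "observed": obs,
                "background_genes": bg,
                "background_proportion": prop,
                "pvalue": pval,
            }
        )
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    return df
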