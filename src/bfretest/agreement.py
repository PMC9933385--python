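"""Agreement between the P-value and Bayes-factor verdicts.

Each retested record is dichotomized twice: by P against alpha = 0.05
(significant / nonsignificant) and by BF01 against 1 (favours the alternative /
favours the null; exactly 1 is a third, indeterminate state). A record is
concordant when both verdicts point the same way. The module computes the
percent agreement, the chance-corrected Cohen kappa on the 2x2 table
(indeterminate records excluded from the table and counted separately), and
the anecdotal-zone cross-tabulation: counts by test kind, by whether BF01
falls in the anecdotal band 1/3 < BF01 < 3, and by P significance.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

if TYPE_CHECKING:  # pragma: no cover
    from .model import RetestResult

__all__ = [
    "DecisionP",
    "DecisionBF",
    "dichotomize",
    "is_concordant",
    "percent_agreement",
    "cohen_kappa",
    "build_crosstab",
    "confusion_matrix",
    "AgreementSummary",
    "summarize_agreement",
    "scatter_export",
]


class DecisionP(str, enum.Enum):
    SIGNIFICANT = "significant"
    NONSIGNIFICANT = "nonsignificant"


class DecisionBF(str, enum.Enum):
    FAVOR_H1 = "favor_H1"
    FAVOR_H0 = "favor_H0"
    INDETERMINATE = "indeterminate"


def dichotomize(p: float, bf01: float, alpha: float = 0.05) -> tuple[DecisionP, DecisionBF]:
    """Binary verdicts: P against alpha, BF01 against 1."""
    if not (0.0 < p <= 1.0):
        raise DomainError(f"p must lie in (0, 1], got {p!r}")
    if not bf01 > 0:
        raise DomainError(f"bf01 must be positive, got {bf01!r}")
    dp = DecisionP.SIGNIFICANT if p < alpha else DecisionP.NONSIGNIFICANT
    if bf01 < 1.0:
        db = DecisionBF.FAVOR_H1
    elif bf01 > 1.0:
        db = DecisionBF.FAVOR_H0
    else:
        db = DecisionBF.INDETERMINATE
    return dp, db


def is_concordant(decision_p: DecisionP, decision_bf: DecisionBF) -> bool:
    """Both verdicts reject, or both retain, the null. Indeterminate never concords."""
    return (decision_p is DecisionP.SIGNIFICANT and decision_bf is DecisionBF.FAVOR_H1) or (
        decision_p is DecisionP.NONSIGNIFICANT and decision_bf is DecisionBF.FAVOR_H0
    )


def percent_agreement(results: Sequence["RetestResult"]) -> float:
    """100 x (number concordant) / (number of results).

    Indeterminate records (BF01 exactly 1) count as discordant here; they are
    reported separately in :class:`AgreementSummary`.
    """
    if len(results) == 0:
        raise DomainError("percent agreement undefined for an empty collection")
    n_conc = sum(1 for r in results if is_concordant(r.decision_p, r.decision_bf))
    return 100.0 * n_conc / len(results)


def cohen_kappa(confusion) -> float:
    """Cohen's kappa for a 2x2 (or square) contingency table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement proportion
    and p_e the chance agreement from the marginals. When the marginals are
    degenerate (p_e = 1, all mass in one row/column pair) the convention is
    kappa = 1 if agreement is perfect, else 0.
    """
    table = np.asarray(confusion, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise DomainError(f"confusion table must be square, got shape {table.shape}")
    if (table < 0).any():
        raise DomainError("confusion table has negative counts")
    total = table.sum()
    if total <= 0:
        raise DomainError("confusion table is empty")
    p_o = np.trace(table) / total
    p_e = float((table.sum(axis=1) / total) @ (table.sum(axis=0) / total))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_matrix(results: Sequence["RetestResult"]) -> np.ndarray:
    """2x2 counts, rows = P verdict (significant, nonsignificant), columns =
    BF verdict (favor_H1, favor_H0). Indeterminate records are excluded."""
    table = np.zeros((2, 2), dtype=int)
    for r in results:
        if r.decision_bf is DecisionBF.INDETERMINATE:
            continue
        i = 0 if r.decision_p is DecisionP.SIGNIFICANT else 1
        j = 0 if r.decision_bf is DecisionBF.FAVOR_H1 else 1
        table[i, j] += 1
    return table


_ANECDOTAL_LO = 1.0 / 3.0
_ANECDOTAL_HI = 3.0


def build_crosstab(results: Sequence["RetestResult"]) -> pd.DataFrame:
    """Anecdotal-zone cross-tabulation, one row per test kind plus a total row.

    Columns (counts, with matching ``*_pct`` percentages of the grand total):

    - ``anecdotal_nonsig`` / ``anecdotal_sig``: 1/3 < BF01 < 3, split by P;
    - ``evidence_h0_nonsig``: BF01 >= 3 with nonsignificant P;
    - ``evidence_h1_sig``: BF01 <= 1/3 with significant P;
    - ``evidence_h0_sig`` / ``evidence_h1_nonsig``: the discordant decisive
      cells, kept so that every record lands in exactly one cell;
    - ``total``: row sum.
    """
    if len(results) == 0:
        raise DomainError("cross-tabulation undefined for an empty collection")
    cells = [
        "anecdotal_nonsig",
        "anecdotal_sig",
        "evidence_h0_nonsig",
        "evidence_h1_sig",
        "evidence_h0_sig",
        "evidence_h1_nonsig",
    ]
    kinds = ["one_sample", "independent", "dependent"]
    counts = {k: dict.fromkeys(cells, 0) for k in kinds}
    for r in results:
        sig = r.decision_p is DecisionP.SIGNIFICANT
        if _ANECDOTAL_LO < r.bf01 < _ANECDOTAL_HI:
            cell = "anecdotal_sig" if sig else "anecdotal_nonsig"
        elif r.bf01 >= _ANECDOTAL_HI:
            cell = "evidence_h0_sig" if sig else "evidence_h0_nonsig"
        else:
            cell = "evidence_h1_sig" if sig else "evidence_h1_nonsig"
        counts[r.test_kind][cell] += 1

    rows = [k for k in kinds if any(counts[k].values())]
    frame = pd.DataFrame([counts[k] for k in rows], index=rows, columns=cells)
    frame.loc["total"] = frame.sum(axis=0)
    frame["total"] = frame[cells].sum(axis=1)
    n_total = int(frame.loc["total", "total"])
    for c in cells + ["total"]:
        frame[c + "_pct"] = (100.0 * frame[c] / n_total).round(2)
    frame.index.name = "test_kind"
    return frame


@dataclass
class AgreementSummary:
    """Concordance of the P and BF verdicts over a set of retested records."""

    n_total: int
    n_concordant: int
    n_indeterminate: int
    percent_agreement: float
    kappa: float
    confusion: np.ndarray
    crosstab: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        ct = {
            str(kind): {col: (float(v) if "_pct" in col else int(v)) for col, v in row.items()}
            for kind, row in self.crosstab.iterrows()
        }
        return {
            "n_total": self.n_total,
            "n_concordant": self.n_concordant,
            "n_indeterminate": self.n_indeterminate,
            "percent_agreement": round(self.percent_agreement, 2),
            "kappa": self.kappa,
            "confusion": {
                "significant_favor_H1": int(self.confusion[0, 0]),
                "significant_favor_H0": int(self.confusion[0, 1]),
                "nonsignificant_favor_H1": int(self.confusion[1, 0]),
                "nonsignificant_favor_H0": int(self.confusion[1, 1]),
            },
            "anecdotal_crosstab": ct,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def summarize_agreement(results: Sequence["RetestResult"]) -> AgreementSummary:
    """Percent agreement, kappa and the anecdotal cross-tab for one result set."""
    if len(results) == 0:
        raise DomainError("agreement summary undefined for an empty collection")
    confusion = confusion_matrix(results)
    n_ind = sum(1 for r in results if r.decision_bf is DecisionBF.INDETERMINATE)
    n_conc = int(confusion[0, 0] + confusion[1, 1])
    return AgreementSummary(
        n_total=len(results),
        n_concordant=n_conc,
        n_indeterminate=n_ind,
        percent_agreement=percent_agreement(results),
        kappa=cohen_kappa(confusion),
        confusion=confusion,
        crosstab=build_crosstab(results),
    )


_SCATTER_AXES = {
    "bf_vs_p": ("p", "bf01"),
    "effect_vs_p": ("p", "effect"),
    "effect_vs_bf": ("bf01", "effect"),
}


def scatter_export(results: Sequence["RetestResult"], which: str) -> pd.DataFrame:
    """Plot-ready table (x, y, test_kind) for one of the three scattergrams.

    Axis values are untransformed; log scaling is a rendering concern.
    """
    if len(results) == 0:
        raise DomainError("scatter export undefined for an empty collection")
    try:
        x_field, y_field = _SCATTER_AXES[which]
    except KeyError:
        raise DomainError(
            f"which must be one of {sorted(_SCATTER_AXES)}, got {which!r}"
        ) from None
    return pd.DataFrame(
        {
            "x": [getattr(r, x_field) for r in results],
            "y": [getattr(r, y_field) for r in results],
            "test_kind": [r.test_kind for r in results],
        }
    )
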