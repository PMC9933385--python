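"""Model/Results interface for the retest pipeline.

``TTestRetest`` is built from a collection of extracted t-test records (or a
DataFrame / CSV in the canonical layout); ``fit()`` runs the staged pipeline —

    verify printed P  →  F-test variance gate  →  t reconstruction
    →  P recomputation  →  JZS BF01  →  Cohen's d  →  evidence labels
    →  P/BF dichotomization  →  agreement summary

— and returns a ``RetestResults`` object carrying one ``RetestResult`` per
retained record, the stage-count log, the agreement summary and a ``summary()``
table. Records whose printed P disagrees with the recomputed one are excluded
before the agreement stage (policy ``"exclude"``, the default) or kept and
flagged (``"flag_only"``). A malformed or uncomputable row never aborts the
run; it is collected into ``rejects`` with its test_id and the failing stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import agreement as agr
from .agreement import AgreementSummary, DecisionBF, DecisionP, dichotomize, summarize_agreement
from .core import (
    Procedure,
    TStat,
    VarianceTest,
    VerificationOutcome,
    VerificationStatus,
    effect_size,
    f_variance_test,
    p_from_t,
    t_from_summary,
    verify_reported_p,
)
from .errors import ConfigError, RetestError
from .jzs import (
    DEFAULT_CUTOFFS,
    EvidenceCutoffs,
    EvidenceLabels,
    JZSConfig,
    bf01_independent,
    bf01_one_sample,
    categorize,
)
from .records import ReportedTest, TestKind, read_tests

__all__ = [
    "PipelineConfig",
    "RetestResult",
    "RetestResults",
    "TTestRetest",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration for one retest run."""

    alpha: float = 0.05
    alpha_f: float = 0.05
    jzs: JZSConfig = field(default_factory=JZSConfig)
    cutoffs: EvidenceCutoffs = field(default_factory=EvidenceCutoffs)
    tolerance_dp: int = 3
    policy: str = "exclude"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not (0.0 < self.alpha_f < 1.0):
            raise ConfigError(f"alpha_f must lie in (0, 1), got {self.alpha_f!r}")
        if self.policy not in ("exclude", "flag_only"):
            raise ConfigError(
                f"policy must be 'exclude' or 'flag_only', got {self.policy!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        """Build from a parsed key-value config file (YAML/JSON mapping)."""
        kwargs: dict = {}
        for key in ("alpha", "alpha_f", "tolerance_dp", "policy"):
            if key in mapping:
                kwargs[key] = mapping[key]
        if "jzs" in mapping:
            kwargs["jzs"] = JZSConfig(**mapping["jzs"])
        if "cutoffs" in mapping:
            kwargs["cutoffs"] = EvidenceCutoffs.from_mapping(mapping["cutoffs"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_f": self.alpha_f,
            "jzs": {
                "rscale": self.jzs.rscale,
                "rel_tolerance": self.jzs.rel_tolerance,
                "limit": self.jzs.limit,
            },
            "cutoffs": {
                "p_edges": list(self.cutoffs.p_edges),
                "effect_edges": list(self.cutoffs.effect_edges),
                "bf_edges": list(self.cutoffs.bf_edges),
            },
            "tolerance_dp": self.tolerance_dp,
            "policy": self.policy,
        }


@dataclass(frozen=True)
class RetestResult:
    """All recomputed quantities for one record."""

    test_id: str
    test_kind: str
    procedure: str
    t: float
    df: float
    p: float
    bf01: float
    effect: float | None
    labels: EvidenceLabels
    verification: VerificationOutcome
    decision_p: DecisionP
    decision_bf: DecisionBF

    def to_row(self) -> dict:
        return {
            "test_id": self.test_id,
            "test_kind": self.test_kind,
            "procedure": self.procedure,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "bf01": self.bf01,
            "effect": self.effect,
            "p_category": self.labels.p_category.value,
            "bf_category": self.labels.bf_category.value,
            "effect_category": self.labels.effect_category.value,
            "verification_status": self.verification.status.value,
            "reported_p": self.verification.reported_p,
            "decision_p": self.decision_p.value,
            "decision_bf": self.decision_bf.value,
        }


RESULT_COLUMNS = (
    "test_id",
    "test_kind",
    "procedure",
    "t",
    "df",
    "p",
    "bf01",
    "effect",
    "p_category",
    "bf_category",
    "effect_category",
    "verification_status",
    "reported_p",
    "decision_p",
    "decision_bf",
)


class TTestRetest:
    """Retest model over a collection of reported t tests.

    Parameters
    ----------
    tests
        Validated (or validatable) :class:`~bfretest.records.ReportedTest`
        records. Invalid records are not fatal: they surface in
        ``fit().rejects``.
    config
        A :class:`PipelineConfig`; defaults reproduce the conventional setup
        (alpha = 0.05, F-gate alpha = 0.05, Cauchy scale 0.707, printed-P
        tolerance 3 decimals, incongruent rows excluded).
    """

    def __init__(self, tests: Sequence[ReportedTest], config: PipelineConfig | None = None):
        self.tests = list(tests)
        self.config = config if config is not None else PipelineConfig()
        self._input_diagnostics: list[str] = []

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, config: PipelineConfig | None = None,
                 ) -> "TTestRetest":
        """Build from an extraction sheet; malformed rows become rejects."""
        records, diagnostics = read_tests(path, errors="collect")
        model = cls(records, config=config)
        model._input_diagnostics = diagnostics
        return model

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: PipelineConfig | None = None,
                       ) -> "TTestRetest":
        """Build from a DataFrame in the canonical column layout."""
        from .errors import RowValidationError, SchemaError
        from .records import _MANDATORY_COLUMNS, _record_from_row

        missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        records: list[ReportedTest] = []
        diagnostics: list[str] = []
        for row_no, (_, row) in enumerate(frame.iterrows(), start=2):
            cells = {k: ("" if pd.isna(v) else str(v)) for k, v in row.items()}
            try:
                records.append(_record_from_row(row_no, cells))
            except RowValidationError as exc:
                diagnostics.append(str(exc))
        model = cls(records, config=config)
        model._input_diagnostics = diagnostics
        return model

    # -- fitting ------------------------------------------------------------

    def _retest_one(self, test: ReportedTest) -> tuple[RetestResult, VarianceTest | None]:
        cfg = self.config
        gate: VarianceTest | None = None
        if test.test_kind is TestKind.INDEPENDENT and test.has_summaries():
            gate = f_variance_test(test.sd1, test.n1, test.sd2, test.n2, alpha_f=cfg.alpha_f)
        tstat = t_from_summary(test, variance_gate=gate)
        p = p_from_t(tstat.t, tstat.df)
        verification = verify_reported_p(p, test, tolerance_dp=cfg.tolerance_dp, alpha=cfg.alpha)
        if test.test_kind is TestKind.INDEPENDENT:
            bf01 = bf01_independent(tstat.t, test.n1, test.n2, cfg.jzs)
        else:
            bf01 = bf01_one_sample(tstat.t, test.n1, cfg.jzs)
        effect = effect_size(test) if test.has_summaries() else None
        labels = categorize(p, bf01, effect if effect is not None else 0.0, cfg.cutoffs)
        decision_p, decision_bf = dichotomize(p, bf01, alpha=cfg.alpha)
        result = RetestResult(
            test_id=test.test_id,
            test_kind=test.test_kind.value,
            procedure=tstat.procedure.value,
            t=tstat.t,
            df=tstat.df,
            p=p,
            bf01=bf01,
            effect=effect,
            labels=labels,
            verification=verification,
            decision_p=decision_p,
            decision_bf=decision_bf,
        )
        return result, gate

    def fit(self) -> "RetestResults":
        """Run every stage over every record and summarize agreement."""
        cfg = self.config
        retained: list[RetestResult] = []
        excluded: list[RetestResult] = []
        rejects: list[tuple[str, str]] = [("<input>", d) for d in self._input_diagnostics]
        for test in self.tests:
            problems = test.problems()
            if problems:
                rejects.append((test.test_id, "validation: " + "; ".join(problems)))
                continue
            try:
                result, _ = self._retest_one(test)
            except RetestError as exc:
                rejects.append((test.test_id, f"retest: {exc}"))
                continue
            if (
                cfg.policy == "exclude"
                and result.verification.status is VerificationStatus.INCONGRUENT
            ):
                excluded.append(result)
            else:
                retained.append(result)
        summary: AgreementSummary | None = None
        agreement_error: str | None = None
        try:
            summary = summarize_agreement(retained)
        except RetestError as exc:
            agreement_error = str(exc)
        stage_counts = {
            "input": len(self.tests) + len(self._input_diagnostics),
            "rejected": len(rejects),
            "verified": len(retained) + len(excluded),
            "excluded_incongruent": len(excluded),
            "retained": len(retained),
        }
        return RetestResults(
            model=self,
            results=retained,
            excluded=excluded,
            rejects=rejects,
            agreement=summary,
            agreement_error=agreement_error,
            stage_counts=stage_counts,
        )


@dataclass
class RetestResults:
    """Per-test recomputations plus the agreement summary for one run."""

    model: TTestRetest
    results: list[RetestResult]
    excluded: list[RetestResult]
    rejects: list[tuple[str, str]]
    agreement: AgreementSummary | None
    agreement_error: str | None
    stage_counts: dict[str, int]

    @property
    def frame(self) -> pd.DataFrame:
        """Retained results, one row per test, canonical column order."""
        return pd.DataFrame(
            [r.to_row() for r in self.results], columns=list(RESULT_COLUMNS)
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def scatter_data(self, which: str) -> pd.DataFrame:
        """(x, y, test_kind) table for 'bf_vs_p', 'effect_vs_p' or 'effect_vs_bf'."""
        return agr.scatter_export(self.results, which)

    def manifest(self) -> dict:
        """Machine-readable provenance: config echo, input hash, stage counts."""
        digest = hashlib.sha256()
        for t in self.model.tests:
            digest.update(repr(t).encode())
        return {
            "config": self.model.config.to_dict(),
            "input_sha256": digest.hexdigest(),
            "stage_counts": self.stage_counts,
        }

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = ["Retest of reported t tests", "=" * 26, ""]
        sc = self.stage_counts
        lines.append(
            f"records: {sc['input']} in, {sc['rejected']} rejected, "
            f"{sc['excluded_incongruent']} excluded (incongruent P), {sc['retained']} retained"
        )
        if self.agreement is not None:
            a = self.agreement
            lines += [
                "",
                f"percent agreement (P at alpha={self.model.config.alpha} vs BF01 at 1): "
                f"{a.percent_agreement:.2f}%  ({a.n_concordant}/{a.n_total} concordant, "
                f"{a.n_indeterminate} indeterminate)",
                f"Cohen's kappa: {a.kappa:.2f}",
                "",
                "anecdotal-zone cross-tabulation (counts):",
                a.crosstab[
                    [
                        "anecdotal_nonsig",
                        "anecdotal_sig",
                        "evidence_h0_nonsig",
                        "evidence_h1_sig",
                        "total",
                    ]
                ].to_string(),
            ]
        else:
            lines.append(f"agreement summary unavailable: {self.agreement_error}")
        return "\n".join(lines)
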