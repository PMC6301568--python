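"""Reading case tables and writing case reports.

The native input is a TSV with one row per discriminating variant — the
casework data are read-count pairs per twin plus an external germline
detection flag, which VCF does not naturally carry across two samples, so a
flat table is the honest format.  Reports are written as TSV (per-variant
block + summary block) or JSON; JSON keeps full precision and round-trips
losslessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .likelihood import CaseResult, ScenarioConfig, VariantObservation, VariantResult
from .posterior import ReadCount

__all__ = [
    "CaseTable",
    "CaseTableError",
    "Report",
    "read_case_tsv",
    "write_case_tsv",
    "write_report",
    "read_report_json",
    "format_value",
]

CASE_COLUMNS = ["variant_id", "chrom", "vA", "wA", "vB", "wB", "germline_detected"]


class CaseTableError(ValueError):
    """Malformed case table; the message names the offending line."""


@dataclass(frozen=True)
class CaseTable:
    observations: list[VariantObservation]
    source: str = ""
    diagnostics: list[str] = field(default_factory=list)


def _parse_count(raw: str, column: str, line: int) -> int:
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise CaseTableError(f"line {line}: column {column!r} must be an integer, got {raw!r}") from None
    if value < 0:
        raise CaseTableError(f"line {line}: column {column!r} must be non-negative, got {value}")
    return value


def read_case_tsv(path: str | Path) -> CaseTable:
    """Parse and validate a case TSV (header + one row per variant)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != CASE_COLUMNS:
        raise CaseTableError(
            f"{path}: header must be exactly {chr(9).join(CASE_COLUMNS)!r}, "
            f"got {chr(9).join(map(str, df.columns))!r}"
        )
    observations: list[VariantObservation] = []
    seen_ids: dict[str, int] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        vid = str(row.variant_id)
        if not vid:
            raise CaseTableError(f"line {line}: variant_id must be non-empty")
        if vid in seen_ids:
            raise CaseTableError(
                f"line {line}: duplicate variant_id {vid!r} (first seen on line {seen_ids[vid]})"
            )
        seen_ids[vid] = line
        if not str(row.chrom):
            raise CaseTableError(f"line {line}: chrom must be non-empty")
        if str(row.germline_detected) not in ("0", "1"):
            raise CaseTableError(
                f"line {line}: germline_detected must be 0 or 1, got {row.germline_detected!r}"
            )
        observations.append(
            VariantObservation(
                variant_id=vid,
                chromosome=str(row.chrom),
                reads_A=ReadCount(_parse_count(row.vA, "vA", line), _parse_count(row.wA, "wA", line)),
                reads_B=ReadCount(_parse_count(row.vB, "vB", line), _parse_count(row.wB, "wB", line)),
                germline_detected=str(row.germline_detected) == "1",
            )
        )
    if not observations:
        raise CaseTableError(f"{path}: no variant rows")
    return CaseTable(observations=observations, source=str(path))


def write_case_tsv(observations: list[VariantObservation], path: str | Path) -> None:
    """Write observations in the canonical case-table dialect."""
    lines = ["\t".join(CASE_COLUMNS)]
    for obs in observations:
        lines.append(
            "\t".join(
                [
                    obs.variant_id,
                    obs.chromosome,
                    str(obs.reads_A.v),
                    str(obs.reads_A.w),
                    str(obs.reads_B.v),
                    str(obs.reads_B.w),
                    "1" if obs.germline_detected else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def format_value(value: float) -> str:
    """Render a number the way the casework tables do.

    Scientific notation (3 significant figures) below 0.01, fixed 4 decimal
    places otherwise; NA for undefined entries.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if value == 0:
        return "0.0000"
    if abs(value) < 1e-2:
        return f"{value:.2e}"
    return f"{value:.4f}"


@dataclass(frozen=True)
class Report:
    """A case result plus the run metadata needed to reproduce it."""

    result: CaseResult
    scenario: str
    prior_alpha: float
    prior_beta: float
    threshold: float
    prior_odds: float
    version: str = ""
    timestamp: str = ""

    @classmethod
    def from_config(cls, result: CaseResult, config: ScenarioConfig, version: str = "") -> "Report":
        return cls(
            result=result,
            scenario=config.scenario,
            prior_alpha=config.prior.alpha,
            prior_beta=config.prior.beta,
            threshold=config.detection_threshold,
            prior_odds=config.prior_odds,
            version=version,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "prior": {"alpha": self.prior_alpha, "beta": self.prior_beta},
            "threshold": self.threshold,
            "prior_odds": self.prior_odds,
            "version": self.version,
            "timestamp": self.timestamp,
            "per_variant": [
                {
                    "variant_id": r.variant_id,
                    "lik_A": r.lik_A,
                    "lik_B": r.lik_B,
                    "lr": r.lr,
                    "informative": r.informative,
                }
                for r in self.result.per_variant
            ],
            "combined_lr": self.result.combined_lr,
            "posterior_odds": self.result.posterior_odds,
            "warnings": list(self.result.warnings),
        }

    def to_tsv(self) -> str:
        lines = ["variant_id\tlik_A\tlik_B\tlr\tlr_full\tinformative"]
        for r in self.result.per_variant:
            lines.append(
                "\t".join(
                    [
                        r.variant_id,
                        format_value(r.lik_A),
                        format_value(r.lik_B),
                        format_value(r.lr) if math.isnan(r.lr) or r.lr < 1 else f"{r.lr:.0f}",
                        repr(r.lr),
                        "1" if r.informative else "0",
                    ]
                )
            )
        lines.append("")
        lines.append("summary\tvalue\tvalue_full")
        lines.append(f"scenario\t{self.scenario}\t{self.scenario}")
        lines.append(f"prior_alpha\t{format_value(self.prior_alpha)}\t{self.prior_alpha!r}")
        lines.append(f"prior_beta\t{format_value(self.prior_beta)}\t{self.prior_beta!r}")
        lines.append(f"combined_lr\t{format_value(self.result.combined_lr)}\t{self.result.combined_lr!r}")
        lines.append(
            f"posterior_odds\t{format_value(self.result.posterior_odds)}\t{self.result.posterior_odds!r}"
        )
        if self.result.warnings:
            lines.append("")
            lines.append("warnings")
            lines.extend(self.result.warnings)
        return "\n".join(lines) + "\n"


def write_report(report: Report, fmt: str, path: str | Path) -> None:
    if fmt == "json":
        Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif fmt == "tsv":
        Path(path).write_text(report.to_tsv())
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")


def read_report_json(path: str | Path) -> CaseResult:
    """Rebuild a CaseResult from a JSON report (lossless round trip)."""
    data = json.loads(Path(path).read_text())
    per_variant = [
        VariantResult(
            variant_id=entry["variant_id"],
            lik_A=entry["lik_A"],
            lik_B=entry["lik_B"],
            lr=entry["lr"],
            informative=entry["informative"],
        )
        for entry in data["per_variant"]
    ]
    return CaseResult(
        per_variant=per_variant,
        combined_lr=data["combined_lr"],
        posterior_odds=data["posterior_odds"],
        warnings=list(data["warnings"]),
    )
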