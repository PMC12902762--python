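"""File I/O: wide response CSVs, label CSVs, reports, session logs.

Exchange formats are deliberately plain: wide CSV (one row per respondent,
``id`` column + one column per item id) for responses, a 0/1 CSV
(``id, mdd, anxiety, ptsd, insomnia``) for reference labels, JSON for
session logs and accuracy reports, markdown for human-readable report
tables.  UTF-8 and decimal points everywhere, regardless of locale.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import dta
from .engine import ScreeningResult
from .instruments import Battery, DISORDERS, ScoringError
from .tiersim import ResponseDataset, results_frame
from ._util import round_half_up

#: Reference-label CSV column -> canonical disorder name.
LABEL_ALIASES = {"mdd": "depression", "depression": "depression",
                 "anxiety": "anxiety", "ptsd": "ptsd", "insomnia": "insomnia"}


def read_wide_responses(
    path: str | Path, battery: Battery, strict: bool = True
) -> ResponseDataset:
    """Read and validate a wide response CSV against the battery."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ScoringError(f"{path}: missing required 'id' column")
    df["id"] = df["id"].astype(str)
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].unique().tolist()
        raise ScoringError(f"{path}: duplicated respondent ids {dupes}")
    df = df.set_index("id")
    return ResponseDataset.from_frame(df, battery, strict=strict)


def write_wide_responses(dataset: ResponseDataset, path: str | Path) -> None:
    dataset.responses.rename_axis("id").to_csv(path)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a reference-label CSV (0/1 cells) into canonical boolean columns."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ScoringError(f"{path}: missing required 'id' column")
    df["id"] = df["id"].astype(str)
    df = df.set_index("id")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        canon = LABEL_ALIASES.get(col.lower())
        if canon:
            out[canon] = df[col].astype(int).astype(bool)
    missing = [d for d in DISORDERS if d not in out.columns]
    if missing:
        raise ScoringError(f"{path}: missing label columns {missing}")
    return out[list(DISORDERS)]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels[list(DISORDERS)].astype(int).rename(
        columns={"depression": "mdd"})
    out.rename_axis("id").to_csv(path)


def write_results(
    results: Mapping[str, ScreeningResult], path: str | Path
) -> None:
    results_frame(results).to_csv(path)


# ---------------------------------------------------------------------------
# Accuracy reports
# ---------------------------------------------------------------------------

def report_to_json(reports: Mapping[str, dta.DTAReport]) -> str:
    """Serialise per-disorder reports at full numeric precision."""
    return json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=1)


def report_from_json(doc: str) -> dict[str, dta.DTAReport]:
    data = json.loads(doc)
    out = {}
    for key, r in data.items():
        table = dta.ConfusionTable(**r["table"])
        def est(e: dict) -> dta.Estimate:
            return dta.Estimate(
                value=e["value"], ci=tuple(e["ci"]) if e["ci"] else None,
                denominator=e["denominator"], defined=e["defined"],
            )
        out[key] = dta.DTAReport(
            table=table,
            sensitivity=est(r["sensitivity"]), specificity=est(r["specificity"]),
            ppv=est(r["ppv"]), npv=est(r["npv"]), accuracy=est(r["accuracy"]),
            kappa=r["kappa"],
        )
    return out


def _fmt_est(e: dta.Estimate) -> str:
    if not e.defined:
        return "undefined"
    lo, hi = e.ci  # type: ignore[misc]
    return (f"{round_half_up(e.value, 1)} "
            f"({round_half_up(lo, 1)}-{round_half_up(hi, 1)})")


def report_to_markdown(reports: Mapping[str, dta.DTAReport]) -> str:
    """Markdown table with the conventional concordance-report columns."""
    head = ("| Disorder | n_pos | Cohen k | Sensitivity, % (95% CI) | "
            "Specificity, % (95% CI) | PPV, % (95% CI) | NPV, % (95% CI) | "
            "Accuracy, % (95% CI) |")
    sep = "|" + "---|" * 8
    lines = [head, sep]
    for key, r in reports.items():
        kappa = "undefined" if r.kappa is None else f"{round_half_up(r.kappa, 2):.2f}"
        lines.append(
            f"| {key} | {r.n_pos_index} | {kappa} | {_fmt_est(r.sensitivity)} | "
            f"{_fmt_est(r.specificity)} | {_fmt_est(r.ppv)} | "
            f"{_fmt_est(r.npv)} | {_fmt_est(r.accuracy)} |"
        )
    return "\n".join(lines) + "\n"


def report_to_csv(reports: Mapping[str, dta.DTAReport]) -> str:
    rows = []
    for key, r in reports.items():
        row = {"disorder": key, "n_pos": r.n_pos_index,
               "kappa": None if r.kappa is None else round_half_up(r.kappa, 2)}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            e: dta.Estimate = getattr(r, name)
            if e.defined:
                row[name] = round_half_up(e.value, 1)
                row[f"{name}_lo"] = round_half_up(e.ci[0], 1)
                row[f"{name}_hi"] = round_half_up(e.ci[1], 1)
            else:
                row[name] = row[f"{name}_lo"] = row[f"{name}_hi"] = None
        rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False)


def write_report(
    reports: Mapping[str, dta.DTAReport], fmt: str = "json"
) -> str:
    """Render reports as ``json`` (full precision), ``markdown`` or ``csv``."""
    if fmt == "json":
        return report_to_json(reports)
    if fmt == "markdown":
        return report_to_markdown(reports)
    if fmt == "csv":
        return report_to_csv(reports)
    raise ValueError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# Run provenance
# ---------------------------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_log(battery: Battery, seed: int | None,
            inputs: Mapping[str, str | Path]) -> dict:
    """Structured provenance record sufficient to reproduce a run."""
    return {
        "battery": battery.name,
        "battery_hash": battery.hash(),
        "seed": seed,
        "inputs": {name: {"path": str(p), "sha256_16": file_checksum(p)}
                   for name, p in inputs.items() if Path(p).exists()},
    }
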