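"""Serialization of verdicts and history reports to JSON / Markdown / CSV."""

from __future__ import annotations

import dataclasses
import json

import pandas as pd

from .sst import SSTVerdict

__all__ = ["verdict_to_dict", "verdict_to_json", "verdict_to_markdown", "verdict_detail_frame"]


def verdict_to_dict(verdict: SSTVerdict) -> dict:
    return {
        "polarity": verdict.polarity,
        "phase": verdict.phase,
        "pass": verdict.passed,
        "recommendation": verdict.recommendation.value,
        "failed_compounds": list(verdict.failed_compounds),
        "missing_compounds": list(verdict.missing_compounds),
        "bias": {
            "flagged": verdict.bias.flagged,
            "sign": verdict.bias.sign,
            "p_value": verdict.bias.p_value,
            "n_used": verdict.bias.n_used,
            "conclusive": verdict.bias.conclusive,
        },
        "n_replicates": verdict.n_replicates,
        "compounds": [dataclasses.asdict(s) for s in verdict.summaries],
    }


def verdict_to_json(verdict: SSTVerdict, indent: int = 2) -> str:
    return json.dumps(verdict_to_dict(verdict), indent=indent)


def verdict_detail_frame(verdict: SSTVerdict) -> pd.DataFrame:
    rows = [dataclasses.asdict(s) for s in verdict.summaries]
    df = pd.DataFrame(rows)
    df["failed"] = df["compound_name"].isin(verdict.failed_compounds)
    df["missing"] = df["compound_name"].isin(verdict.missing_compounds)
    return df


def verdict_to_markdown(verdict: SSTVerdict) -> str:
    lines = [
        f"## SST verdict — {verdict.polarity} / {verdict.phase}",
        "",
        f"**Result:** {'PASS' if verdict.passed else 'FAIL'} — "
        f"recommendation **{verdict.recommendation.value}** "
        f"({verdict.n_replicates} replicates)",
        "",
    ]
    if verdict.bias.conclusive and verdict.bias.p_value is not None:
        sign = {1: "positive", -1: "negative", 0: "none"}[verdict.bias.sign]
        lines.append(
            f"Bias check: p = {verdict.bias.p_value:.4g} "
            f"({'flagged, ' + sign + ' bias' if verdict.bias.flagged else 'not flagged'})"
        )
    else:
        lines.append("Bias check: inconclusive (too few compounds)")
    lines += ["", "| compound | n | mean ppm | sd ppm | status |", "| --- | ---: | ---: | ---: | --- |"]
    for s in verdict.summaries:
        status = []
        if s.compound_name in verdict.failed_compounds:
            status.append("THRESHOLD")
        if s.compound_name in verdict.missing_compounds:
            status.append("MISSING")
        mean = f"{s.mean_error:.3f}" if s.mean_error is not None else "—"
        sd = f"{s.sd_error:.3f}" if s.sd_error is not None else "—"
        lines.append(
            f"| {s.compound_name} | {s.n} | {mean} | {sd} | {'/'.join(status) or 'ok'} |"
        )
    return "\n".join(lines)
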