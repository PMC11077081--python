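"""qPCR calculi: restriction-protection resection, ΔΔCq expression, ChIP %input.

The resection assay digests genomic DNA with a restriction enzyme whose site
lies inside each amplicon; double-stranded (unresected) template is cut and
fails to amplify, while resected single-stranded DNA is protected.  The
digested-vs-mock Cq shift converts to a single-stranded fraction by

    ssDNA% = 1 / (2^(dCt - 1) + 0.5) * 100,        dCt = Cq_digested - Cq_mock

which is exact under 100% amplification efficiency for a double-stranded
genome in which one of the two strands of a resected site survives digestion.
dCt = 0 (digestion changes nothing) means fully protected: ssDNA% = 100.

Relative expression uses the standard ΔΔCq with a housekeeping normaliser
(fold = 2^-(ΔCq - ΔCq_control)); ChIP enrichment is expressed as percent of
input after correcting the input Cq for the input dilution fraction.
Amplification efficiency is fixed at 2.0 per cycle throughout; replicate Cq
values are averaged arithmetically before any difference is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResectionResult",
    "PairingError",
    "ssdna_percent",
    "resection_profile",
    "relative_expression",
    "expression_table",
    "chip_percent_input",
    "chip_table",
]


class PairingError(ValueError):
    """A (condition, amplicon) pair is missing its mock or digested arm."""


@dataclass(frozen=True)
class ResectionResult:
    amplicon: str
    condition: str
    delta_ct: float
    ssdna_pct: float
    fold_vs_control: float | None = None
    clamped: bool = False  # ΔCt < 0 clamped to 0 (full protection, QC flag)
    negative_control: bool = False


def ssdna_percent(
    ct_digested: float,
    ct_mock: float,
    amplicon: str = "",
    condition: str = "",
) -> ResectionResult:
    """Single-stranded DNA percentage from digested and mock mean Cq values.

    ΔCt = Cq_digested − Cq_mock; a negative ΔCt (digested amplifying earlier
    than mock, possible only through measurement noise near full protection)
    is clamped to 0 and flagged.
    """
    if not (np.isfinite(ct_digested) and np.isfinite(ct_mock)):
        raise PairingError(f"missing mock or digested Cq for {amplicon or 'amplicon'}")
    delta = ct_digested - ct_mock
    clamped = delta < 0
    delta_eff = max(delta, 0.0)
    pct = 100.0 / (2.0 ** (delta_eff - 1.0) + 0.5)
    return ResectionResult(amplicon, condition, delta, pct, clamped=clamped)


def resection_profile(
    panel: pd.DataFrame,
    control_condition: str | None = None,
    negative_controls: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-amplicon, per-condition ssDNA% from a replicate Cq table.

    ``panel`` columns: condition, amplicon, digestion (mock|digested),
    replicate, cq (a ``role`` column, if present, marks negative-control
    amplicons).  Replicates are averaged per arm; per-arm SDs are propagated
    into the report.  With ``control_condition`` set, each amplicon also gets
    ssDNA% fold change versus the control.
    """
    required = {"condition", "amplicon", "digestion", "cq"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    neg = set(negative_controls)
    if "role" in panel.columns:
        neg |= set(panel.loc[panel["role"] == "negative_control", "amplicon"])

    grouped = panel.groupby(["condition", "amplicon", "digestion"])["cq"].agg(
        ["mean", "std", "count"]
    )
    rows = []
    for (condition, amplicon), sub in panel.groupby(["condition", "amplicon"]):
        arms = set(sub["digestion"])
        if not {"mock", "digested"} <= arms:
            raise PairingError(
                f"amplicon {amplicon!r} in condition {condition!r} lacks "
                f"{sorted({'mock', 'digested'} - arms)} replicates"
            )
        mock = grouped.loc[(condition, amplicon, "mock")]
        dig = grouped.loc[(condition, amplicon, "digested")]
        res = ssdna_percent(dig["mean"], mock["mean"], amplicon, condition)
        rows.append(
            {
                "condition": condition,
                "amplicon": amplicon,
                "cq_mock_mean": mock["mean"],
                "cq_mock_sd": mock["std"],
                "cq_digested_mean": dig["mean"],
                "cq_digested_sd": dig["std"],
                "n_replicates": int(min(mock["count"], dig["count"])),
                "delta_ct": res.delta_ct,
                "clamped": res.clamped,
                "ssdna_pct": res.ssdna_pct,
                "negative_control": amplicon in neg,
            }
        )
    out = pd.DataFrame(rows)
    if control_condition is not None:
        if control_condition not in set(out["condition"]):
            raise ValueError(f"control condition {control_condition!r} not in panel")
        ctrl = out[out["condition"] == control_condition].set_index("amplicon")[
            "ssdna_pct"
        ]
        out["fold_vs_control"] = [
            row.ssdna_pct / ctrl[row.amplicon] if row.amplicon in ctrl.index else np.nan
            for row in out.itertuples(index=False)
        ]
    return out


def relative_expression(
    cq_target: float,
    cq_housekeeping: float,
    cq_target_ctrl: float | None = None,
    cq_housekeeping_ctrl: float | None = None,
) -> float:
    """Fold expression by ΔΔCq against a housekeeping gene.

    ΔCq = Cq_target − Cq_housekeeping per condition; with a control condition
    the fold change is 2^−(ΔCq − ΔCq_ctrl); without one, 2^−ΔCq (expression
    relative to the housekeeping gene itself).
    """
    dcq = cq_target - cq_housekeeping
    if cq_target_ctrl is None and cq_housekeeping_ctrl is None:
        return 2.0 ** (-dcq)
    if cq_target_ctrl is None or cq_housekeeping_ctrl is None:
        raise ValueError("control requires both target and housekeeping Cq")
    dcq_ctrl = cq_target_ctrl - cq_housekeeping_ctrl
    return 2.0 ** (-(dcq - dcq_ctrl))


def expression_table(
    table: pd.DataFrame, control_condition: str | None = None
) -> pd.DataFrame:
    """ΔΔCq expression from a replicate table.

    Columns: condition, target, role (target|housekeeping), cq.  Replicates
    are averaged per (condition, target, role); each target is normalised to
    the housekeeping Cq of its condition, then (optionally) to the control
    condition.
    """
    required = {"condition", "target", "role", "cq"}
    if missing := required - set(table.columns):
        raise ValueError(f"expression table is missing columns: {sorted(missing)}")
    means = table.groupby(["condition", "target", "role"])["cq"].mean()
    rows = []
    for condition in sorted(table["condition"].unique()):
        hk = means.xs(condition, level="condition")
        hk_cq = hk.xs("housekeeping", level="role")
        if len(hk_cq) != 1:
            raise ValueError(
                f"condition {condition!r} needs exactly one housekeeping target"
            )
        hk_cq = float(hk_cq.iloc[0])
        for (target, role), cq in hk.items():
            if role != "target":
                continue
            rows.append(
                {
                    "condition": condition,
                    "target": target,
                    "cq_target": float(cq),
                    "cq_housekeeping": hk_cq,
                    "rel_expression": relative_expression(float(cq), hk_cq),
                }
            )
    out = pd.DataFrame(rows)
    if control_condition is not None:
        ctrl = out[out["condition"] == control_condition].set_index("target")[
            "rel_expression"
        ]
        out["fold_vs_control"] = [
            r.rel_expression / ctrl[r.target] if r.target in ctrl.index else np.nan
            for r in out.itertuples(index=False)
        ]
    return out


def chip_table(table: pd.DataFrame) -> pd.DataFrame:
    """ChIP percent-input from a replicate table.

    Columns: condition, target (amplicon), role (IP|input), input_fraction,
    cq.  Replicates are averaged per arm before the percent-input formula.
    """
    required = {"condition", "target", "role", "input_fraction", "cq"}
    if missing := required - set(table.columns):
        raise ValueError(f"ChIP table is missing columns: {sorted(missing)}")
    means = table.groupby(["condition", "target", "role"])["cq"].mean()
    fracs = table.groupby(["condition", "target"])["input_fraction"].first()
    rows = []
    for (condition, target), frac in fracs.items():
        try:
            cq_ip = float(means.loc[(condition, target, "IP")])
            cq_in = float(means.loc[(condition, target, "input")])
        except KeyError as exc:
            raise PairingError(
                f"{target!r} in {condition!r} lacks an IP or input arm"
            ) from exc
        rows.append(
            {
                "condition": condition,
                "target": target,
                "cq_ip": cq_ip,
                "cq_input": cq_in,
                "input_fraction": float(frac),
                "percent_input": chip_percent_input(cq_in, float(frac), cq_ip),
            }
        )
    return pd.DataFrame(rows)


def chip_percent_input(
    cq_input: float, input_fraction: float, cq_ip: float
) -> float:
    """ChIP enrichment as percent of input chromatin.

    The input aliquot is only ``input_fraction`` of the chromatin used per
    IP, so its Cq is first shifted by log2(1/input_fraction) to the
    full-input equivalent; %input = 100 * 2^(adjusted_input_Cq − IP_Cq).
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = cq_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - cq_ip)
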