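"""Evaluation metrics and table-style reports.

Accuracy of the estimated stance-phase kinetics is summarised the way
gait-estimation studies report it: a root-mean-square error normalized
to the amplitude (max - min) of the measured curve of each stance phase
(NRMSE, in percent), the coefficient of determination R^2 per stance
phase, the mean absolute error of detected gait-event times, and the
mean absolute error of estimated walking speeds.  NRMSE and R^2 are
always computed per stance phase and then averaged, never on
concatenated data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "nrmse",
    "r_squared",
    "event_mae",
    "EvalReport",
    "build_report",
    "GRF_COP_CHANNELS",
    "TORQUE_CHANNELS",
]

GRF_COP_CHANNELS = ("grf_ml", "grf_ap", "grf_vertical", "cop_ml", "cop_ap")
TORQUE_CHANNELS = (
    "hip_abad",
    "hip_ef",
    "hip_erir",
    "knee_abad",
    "knee_fe",
    "knee_erir",
    "ankle_pfdf",
)


def nrmse(pred: np.ndarray, meas: np.ndarray) -> float:
    """RMSE normalized by the measured amplitude of the stance phase, in %.

    Raises ``ValueError`` for curves of unequal length or zero measured
    amplitude (a degenerate stance that carries no signal to normalize
    against).
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("pred and meas must have equal length")
    amp = float(np.max(meas) - np.min(meas))
    if amp <= 1e-9 * max(1.0, float(np.max(np.abs(meas)))):
        raise ValueError("measured amplitude is numerically zero; NRMSE undefined")
    rmse = math.sqrt(float(np.mean((pred - meas) ** 2)))
    return 100.0 * rmse / amp


def r_squared(pred: np.ndarray, meas: np.ndarray) -> float:
    """Coefficient of determination about the stance mean; may be negative."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("pred and meas must have equal length")
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    if ss_tot <= 1e-18 * max(1.0, float(np.max(np.abs(meas))) ** 2) * len(meas):
        raise ValueError("measured variance is numerically zero; R^2 undefined")
    ss_res = float(np.sum((pred - meas) ** 2))
    return 1.0 - ss_res / ss_tot


def _match_events(detected: np.ndarray, truth: np.ndarray, window: float):
    """Greedy nearest-neighbour one-to-one matching within ``window`` seconds."""
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    pairs = []
    # candidate pairs ordered by |dt| give a symmetric greedy matching
    cand = sorted(
        (abs(d - t), i, j)
        for j, t in enumerate(truth)
        for i, d in enumerate(detected)
        if abs(d - t) <= window
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((detected[i], truth[j]))
    unmatched = (len(detected) - len(pairs)) + (len(truth) - len(pairs))
    return pairs, unmatched


def event_mae(detected, truth, window: float = 0.25) -> dict:
    """Mean absolute error of detected event times against ground truth.

    ``detected`` and ``truth`` map event type (e.g. ``"HS"``, ``"TO"``)
    to arrays of times in seconds.  Events are matched one-to-one by
    nearest neighbour within ``window`` seconds (about half a stride);
    unmatched events are counted and excluded from the MAE.  Returns per
    event type ``{"mae": s, "n": matched, "unmatched": count}``.
    """
    out = {}
    for kind in truth:
        det = np.asarray(detected.get(kind, []), dtype=float)
        pairs, unmatched = _match_events(det, np.asarray(truth[kind]), window)
        errs = [abs(d - t) for d, t in pairs]
        out[kind] = {
            "mae": float(np.mean(errs)) if errs else float("nan"),
            "n": len(errs),
            "unmatched": int(unmatched),
        }
    return out


@dataclass
class EvalReport:
    """Per-channel, per-speed accuracy tables of a completed evaluation.

    ``table`` has one row per (channel, speed) cell and a pooled row per
    channel (speed = "all"), with NRMSE and R^2 mean and SD over stance
    phases plus the stance count.  Degenerate stances (zero measured
    amplitude) are excluded and counted, never reported as zero error.
    """

    table: pd.DataFrame
    event_errors: dict = field(default_factory=dict)
    speed_mae: float = float("nan")
    n_excluded: int = 0
    notes: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Stance-phase estimation accuracy (mean +/- SD over stances)", ""]
        if not self.table.empty:
            tab = self.table.copy()
            tab["NRMSE (%)"] = tab.apply(
                lambda r: f"{r.nrmse_mean:.2f} +/- {r.nrmse_sd:.2f}", axis=1
            )
            tab["R^2"] = tab.apply(
                lambda r: f"{r.r2_mean:.2f} +/- {r.r2_sd:.2f}", axis=1
            )
            lines.append(
                tab[["channel", "speed", "n", "NRMSE (%)", "R^2"]].to_string(
                    index=False
                )
            )
        if self.event_errors:
            lines += ["", "Gait-event mean absolute error (s):"]
            for kind, d in sorted(self.event_errors.items()):
                lines.append(
                    f"  {kind}: {d['mae']:.4f}  (n={d['n']}, unmatched={d['unmatched']})"
                )
        if not math.isnan(self.speed_mae):
            lines += ["", f"Walking-speed MAE: {self.speed_mae:.3f} m/s"]
        if self.n_excluded:
            lines += ["", f"Excluded degenerate stances: {self.n_excluded}"]
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines) + "\n"


def build_report(
    predictions,
    event_errors: dict | None = None,
    speed_mae: float = float("nan"),
) -> EvalReport:
    """Aggregate per-stance predictions into an :class:`EvalReport`.

    ``predictions`` is an iterable of records with keys ``channel``,
    ``speed``, ``pred`` and ``meas`` (stance curves in physical units).
    NRMSE/R^2 are computed per stance and averaged per (channel, speed)
    cell; the pooled row is the stance-weighted mean over speeds.
    """
    rows = []
    n_excluded = 0
    notes = []
    per_cell: dict = {}
    for rec in predictions:
        ch, sp = rec["channel"], rec["speed"]
        try:
            e = nrmse(rec["pred"], rec["meas"])
            r2 = r_squared(rec["pred"], rec["meas"])
        except ValueError:
            n_excluded += 1
            continue
        per_cell.setdefault((ch, sp), []).append((e, r2))
        per_cell.setdefault((ch, "all"), []).append((e, r2))

    def key(cell):
        ch, sp = cell
        order = list(GRF_COP_CHANNELS + TORQUE_CHANNELS)
        ch_i = order.index(ch) if ch in order else len(order)
        sp_k = (1, 0.0) if sp == "all" else (0, float(sp))
        return (ch_i, ch, sp_k)

    for (ch, sp) in sorted(per_cell, key=key):
        vals = np.array(per_cell[(ch, sp)])
        rows.append(
            {
                "channel": ch,
                "speed": sp,
                "n": len(vals),
                "nrmse_mean": float(vals[:, 0].mean()),
                "nrmse_sd": float(vals[:, 0].std(ddof=1)) if len(vals) > 1 else 0.0,
                "r2_mean": float(vals[:, 1].mean()),
                "r2_sd": float(vals[:, 1].std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    if n_excluded:
        notes.append(
            f"{n_excluded} stance curves had zero measured amplitude and were excluded"
        )
    table = pd.DataFrame(
        rows,
        columns=["channel", "speed", "n", "nrmse_mean", "nrmse_sd", "r2_mean", "r2_sd"],
    )
    return EvalReport(
        table=table,
        event_errors=event_errors or {},
        speed_mae=speed_mae,
        n_excluded=n_excluded,
        notes=notes,
    )
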