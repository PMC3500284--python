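"""Model quality metrics and benchmark aggregation.

RMSD via Kabsch superposition, length-normalized RMSD100, the contact order
family (CO, RCO, NCO), contact recovery against a native structure,
native-like classification counts over benchmark tables, and the
non-symmetric move-correlation statistic over search trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_fit


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# RMSD family
# ---------------------------------------------------------------------------


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD over rigid superpositions (rotation+translation, no
    reflection) of two index-matched CA coordinate sets."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise MetricsError("coordinate sets must both be (n, 3)")
    if len(a) < 3:
        raise MetricsError("need at least 3 points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise MetricsError("non-finite coordinates")
    R, t = kabsch_fit(a, b)
    moved = a @ R.T + t
    return float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))


def rmsd100(rmsd: float, n: int) -> float:
    """RMSD normalized to a 100-residue protein: rmsd / (1 + ln sqrt(n/100)).

    Undefined (raises) for n small enough that the denominator is <= 0
    (n <= 100 * e**-2, i.e. n <= 13).
    """
    if n < 1 or rmsd < 0:
        raise MetricsError("need n >= 1 and rmsd >= 0")
    denom = 1.0 + math.log(math.sqrt(n / 100.0))
    if denom <= 0:
        raise MetricsError(f"RMSD100 undefined for n={n} (denominator <= 0)")
    return rmsd / denom


# ---------------------------------------------------------------------------
# Contact order family and contact recovery
# ---------------------------------------------------------------------------


def _contact_pairs(indices, cb_coords, cutoff: float, min_sep: int):
    idx = np.asarray(indices)
    cb = np.asarray(cb_coords, dtype=float)
    if len(idx) != len(cb):
        raise MetricsError("indices and coordinates differ in length")
    d = np.sqrt(((cb[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
    sep = np.abs(idx[:, None] - idx[None, :])
    mask = (sep >= min_sep) & (d < cutoff)
    mask &= np.triu(np.ones_like(mask, dtype=bool), k=1)
    ii, jj = np.nonzero(mask)
    return set(zip(idx[ii].tolist(), idx[jj].tolist()))


def contact_order(indices, cb_coords, seq_length: int,
                  cutoff: float = 8.0, min_sep: int = 1):
    """(CO, RCO, NCO) from CB contacts.

    Contacts are unordered residue pairs with |i-j| >= min_sep and CB
    distance < cutoff; CO is their mean sequence separation, RCO = CO/L,
    NCO = CO**2/L with L the full sequence length.
    """
    if len(indices) < 2:
        raise MetricsError("need at least 2 residues")
    pairs = _contact_pairs(indices, cb_coords, cutoff, min_sep)
    if not pairs:
        raise MetricsError("no contacts: contact order undefined")
    seps = [abs(i - j) for i, j in pairs]
    co = float(np.mean(seps))
    return co, co / seq_length, co * co / seq_length


def contact_recovery(model_indices, model_cb, native_indices, native_cb,
                     min_sep: int = 12, cutoff: float = 8.0) -> float:
    """Percent of native contacts present in the model.

    Only residues present in both structures are compared; contacts use the
    12-residue minimum sequence separation and the 8 A CB cutoff.
    """
    model_indices = np.asarray(model_indices)
    native_indices = np.asarray(native_indices)
    common = np.intersect1d(model_indices, native_indices)
    m_sel = np.isin(model_indices, common)
    n_sel = np.isin(native_indices, common)
    m_pairs = _contact_pairs(
        model_indices[m_sel], np.asarray(model_cb)[m_sel], cutoff, min_sep
    )
    n_pairs = _contact_pairs(
        native_indices[n_sel], np.asarray(native_cb)[n_sel], cutoff, min_sep
    )
    if not n_pairs:
        raise MetricsError("native structure has no qualifying contacts")
    return 100.0 * len(m_pairs & n_pairs) / len(n_pairs)


@dataclass
class QualityMetrics:
    rmsd: float
    rmsd100: float
    co: float
    rco: float
    nco: float
    cr: float


# ---------------------------------------------------------------------------
# Benchmark tables
# ---------------------------------------------------------------------------

RMSD_COLUMNS = (
    "rmsd100_native_sse",
    "rmsd100_native_complete",
    "rmsd100_predicted_sse",
    "rmsd100_predicted_complete",
    "rmsd100_comparator",
)
CR_COLUMNS = (
    "cr_native_sse",
    "cr_native_complete",
    "cr_predicted_sse",
    "cr_predicted_complete",
    "cr_comparator",
)


def benchmark_summary(table: pd.DataFrame, rmsd_cut: float = 8.0,
                      cr_cut: float = 20.0) -> dict:
    """Headline statistics of a best-model benchmark table.

    Per RMSD100 column: count of proteins strictly below ``rmsd_cut``
    (native-like by topology), mean and sample SD.  Per CR column: count
    strictly above ``cr_cut``, mean and SD.  Improvement counts are rows
    where a method column beats the comparator column of the same metric
    (strictly smaller RMSD100 / strictly larger CR).
    """
    if table.empty:
        raise MetricsError("empty benchmark table")
    out = {"n": int(len(table))}
    for col in RMSD_COLUMNS:
        if col in table:
            vals = table[col].astype(float)
            out[f"{col}_below_cut"] = int((vals < rmsd_cut).sum())
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_sd"] = float(vals.std(ddof=1))
    for col in CR_COLUMNS:
        if col in table:
            vals = table[col].astype(float)
            out[f"{col}_above_cut"] = int((vals > cr_cut).sum())
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_sd"] = float(vals.std(ddof=1))
    if "rmsd100_comparator" in table:
        comp = table["rmsd100_comparator"].astype(float)
        for col in RMSD_COLUMNS[:4]:
            if col in table:
                out[f"{col}_improved_vs_comparator"] = int(
                    (table[col].astype(float) < comp).sum()
                )
    if "cr_comparator" in table:
        comp = table["cr_comparator"].astype(float)
        for col in CR_COLUMNS[:4]:
            if col in table:
                out[f"{col}_improved_vs_comparator"] = int(
                    (table[col].astype(float) > comp).sum()
                )
    return out


# ---------------------------------------------------------------------------
# Move correlation
# ---------------------------------------------------------------------------


def _steps_of(trajectory):
    steps = []
    for rec in trajectory:
        if hasattr(rec, "move"):
            steps.append((rec.move, rec.outcome))
        else:
            move, outcome = rec[0], rec[1]
            steps.append((move, outcome))
    return steps


def move_correlation(trajectories, window: int = 50,
                     move_names=None) -> pd.DataFrame:
    """Non-symmetric move correlation matrix C(i -> j).

    f1(i,j): fraction of j-improved steps preceded by an i accepted-or-
    improved step within the previous ``window`` steps; f2(i): fraction of
    i moves leading to improved; f3(i): fraction of i moves leading to
    improved-or-accepted.  C(i -> j) = log10(f1/f3); if any of f1, f2, f3
    is 0 the value is floored at -3.
    """
    trajs = [_steps_of(t) for t in trajectories]
    seen = sorted({m for t in trajs for m, _ in t})
    if move_names is None:
        move_names = seen
    else:
        unknown = set(seen) - set(move_names)
        if unknown:
            raise MetricsError(f"unknown move names: {sorted(unknown)}")
    names = list(move_names)
    n_i = {m: 0 for m in names}           # total uses of move i
    n_improved = {m: 0 for m in names}    # i -> improved
    n_acc_imp = {m: 0 for m in names}     # i -> improved or accepted
    j_improved = {m: 0 for m in names}    # improved steps of move j
    preceded = {(i, j): 0 for i in names for j in names}
    for steps in trajs:
        for k, (move, outcome) in enumerate(steps):
            n_i[move] += 1
            if outcome == "improved":
                n_improved[move] += 1
            if outcome in ("improved", "accepted"):
                n_acc_imp[move] += 1
            if outcome == "improved":
                j_improved[move] += 1
                lo = max(0, k - window)
                predecessors = {
                    m for m, out in steps[lo:k]
                    if out in ("improved", "accepted")
                }
                for m in predecessors:
                    preceded[(m, move)] += 1
    mat = np.full((len(names), len(names)), -3.0)
    for a, mi in enumerate(names):
        f2 = n_improved[mi] / n_i[mi] if n_i[mi] else 0.0
        f3 = n_acc_imp[mi] / n_i[mi] if n_i[mi] else 0.0
        for b, mj in enumerate(names):
            f1 = preceded[(mi, mj)] / j_improved[mj] if j_improved[mj] else 0.0
            if f1 == 0.0 or f2 == 0.0 or f3 == 0.0:
                mat[a, b] = -3.0
            else:
                mat[a, b] = math.log10(f1 / f3)
    return pd.DataFrame(mat, index=names, columns=names)
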