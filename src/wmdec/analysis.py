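"""Aggregation of trial records into the model's dependent measures.

Condition means (correct, non-timeout RTs), interpolated spans, orthogonal
switch contrasts, observed-versus-simulated Pearson correlations, and the
weighted combination of chunking variants.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Condition summaries
# ---------------------------------------------------------------------------

def rt_summary(df: pd.DataFrame, by):
    """Mean RT over correct, non-timeout trials plus accuracy, per cell."""
    valid = df[df["response"] != "TIMEOUT"]
    correct = valid[valid["correct"] == 1]
    out = correct.groupby(by)["rt_ms"].mean().rename("rt_ms").to_frame()
    out["accuracy"] = df.groupby(by)["correct"].mean()
    out["n_trials"] = df.groupby(by).size()
    return out.reset_index()


def subject_cell_means(df: pd.DataFrame, by, value="rt_ms",
                       correct_only=True):
    d = df[df["response"] != "TIMEOUT"] if value == "rt_ms" else df
    if correct_only and value == "rt_ms":
        d = d[d["correct"] == 1]
    return d.groupby(["subject"] + list(by))[value].mean().reset_index()


# ---------------------------------------------------------------------------
# Span estimation
# ---------------------------------------------------------------------------

def estimate_span(proportions, lengths):
    """Length at which the proportion-correct curve crosses 0.5.

    Linear interpolation between the lengths bracketing 0.5 (first downward
    crossing); all proportions above 0.5 give the longest length, all below
    give the shortest.
    """
    p = list(proportions)
    ln = list(lengths)
    if len(p) != len(ln) or len(p) < 1:
        raise ValueError("proportions and lengths must align")
    if all(x > 0.5 for x in p):
        return float(ln[-1])
    if all(x < 0.5 for x in p):
        return float(ln[0])
    for i in range(len(p) - 1):
        hi, lo = p[i], p[i + 1]
        if hi >= 0.5 >= lo and hi > lo:
            return ln[i] + (hi - 0.5) / (hi - lo) * (ln[i + 1] - ln[i])
    # curve touches 0.5 exactly or is non-monotone without a bracket
    for i, x in enumerate(p):
        if x == 0.5:
            return float(ln[i])
    return float(ln[-1]) if p[-1] > 0.5 else float(ln[0])


def partial_credit_span(df: pd.DataFrame, lengths, group=None):
    """Sum over lengths of the mean proportion recalled in position.

    A length-weighted span score in items: perfect recall at every length
    gives the maximum list length.
    """
    d = df.copy()
    d["prop"] = d["span"] / d["length"]
    per_len = d.groupby("length")["prop"].mean()
    return float(sum(per_len.get(n, 0.0) for n in lengths))


# ---------------------------------------------------------------------------
# Orthogonal contrasts for the 2x2 transition design
# ---------------------------------------------------------------------------

#: order of means: (task rep, dim rep), (rep, sw), (sw, rep), (sw, sw)
CONTRASTS = {
    "flat": (1.0, -1 / 3, -1 / 3, -1 / 3),       # repetition vs any change
    "single_vs_both": (0.0, 0.5, 0.5, -1.0),     # one component vs both
    "task_vs_dim": (0.0, -1.0, 1.0, 0.0),        # task-only vs dim-only
}


def orthogonal_contrasts(means):
    """Contrast effects and percentage of between-cell variance explained.

    `means` are the four cell means in the order rr, rs, sr, ss (task
    transition x dimension transition).
    """
    m = np.asarray(means, dtype=float)
    if m.shape != (4,):
        raise ValueError("need exactly four cell means")
    grand = m.mean()
    total_ss = float(((m - grand) ** 2).sum())
    out = {}
    for name, w in CONTRASTS.items():
        w = np.asarray(w)
        effect = float(w @ m)
        ss = effect ** 2 / float(w @ w)
        share = 100.0 * ss / total_ss if total_ss > 0 else 0.0
        out[name] = {"effect": effect, "ss": ss, "pct_variance": share}
    return out


# ---------------------------------------------------------------------------
# Fit to the observed means
# ---------------------------------------------------------------------------

def fit_observed(simulated, observed):
    """Pearson product-moment correlation with df = n - 2."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("mean vectors must have equal length")
    n = sim.size
    if n < 3:
        raise ValueError("need at least three paired means")
    r, p = stats.pearsonr(sim, obs)
    return {"r": float(r), "df": n - 2, "p": float(p)}


# ---------------------------------------------------------------------------
# Chunk-variant aggregation
# ---------------------------------------------------------------------------

def combine_chunk_variants(p_none, p_two, p_three, observed=None,
                           mode="fitted"):
    """Combine the three chunking simulations into one proportion curve.

    fixed-average: mean of the no-chunk curve and the list-type-congruent
    chunk curve (the caller supplies the congruent variant as `p_two`).
    fitted: least-squares weights w >= 0 with sum(w) in [0.95, 1.05]
    minimising the squared error to the observed proportions.
    """
    P = np.column_stack([np.asarray(p, dtype=float)
                         for p in (p_none, p_two, p_three)])
    if mode == "fixed-average":
        w = np.array([0.5, 0.5, 0.0])
        return P @ w, w
    if observed is None:
        raise ValueError("fitted mode needs observed proportions")
    y = np.asarray(observed, dtype=float)
    spread = float(P.std(axis=1).max())
    if spread < 1e-9:
        raise ValueError("variant outputs are identical; "
                         "weights are unidentifiable")

    def loss(w):
        return float(((P @ w - y) ** 2).sum())

    cons = [{"type": "ineq", "fun": lambda w: w.sum() - 0.95},
            {"type": "ineq", "fun": lambda w: 1.05 - w.sum()}]
    res = optimize.minimize(loss, x0=np.array([1 / 3, 1 / 3, 1 / 3]),
                            bounds=[(0, None)] * 3, constraints=cons,
                            method="SLSQP")
    w = res.x
    return P @ w, w


# ---------------------------------------------------------------------------
# Observed fixtures (printed human means shipped as CSV)
# ---------------------------------------------------------------------------

@dataclass
class ObservedFixture:
    study: str
    table: str
    frame: pd.DataFrame = field(repr=False, default=None)


def load_observed(name: str) -> ObservedFixture:
    text = resources.files("wmdec.fixtures").joinpath(name).read_text()
    frame = pd.read_csv(io.StringIO(text))
    study = name.split("_")[1].split(".")[0]
    return ObservedFixture(study=study, table=name, frame=frame)
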