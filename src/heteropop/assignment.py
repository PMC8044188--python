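"""Heterotic-group identity assignment from admixture Q values.

Every line gets a default ID: the group with its maximum Q value (argmax,
ties broken by column order and flagged).  Because the argmax becomes
unreliable when the top Q value is near or below 0.5, an adjusted ID is
also assigned.  With A the top group (Q_A) and B the runner-up (Q_B):

    A        if Q_A > 0.5 and Q_A - Q_B > 0.1
    A_Para   if (Q_A > 0.5 and Q_A - Q_B < 0.1)
             or (Q_A <= 0.5 and Q_A - Q_B >= 0.15)
    Mixed    otherwise

The boundary Q_A - Q_B == 0.1 (with Q_A > 0.5), excluded by both strict
inequalities of the rule, resolves to the clear assignment A and is flagged
as a boundary case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import LineRegistry


@dataclass
class AssignmentThresholds:
    q_major: float = 0.5
    delta_clear: float = 0.1
    delta_para: float = 0.15

    def __post_init__(self) -> None:
        for name in ("q_major", "delta_clear", "delta_para"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def default_id(q_row, labels):
    """Argmax group label; returns (label, tie_flag)."""
    q = np.asarray(q_row, dtype=float)
    top = int(np.argmax(q))
    tie = bool(np.sum(np.isclose(q, q[top], atol=1e-12)) > 1)
    return labels[top], tie


def adjusted_id(q_row, labels, thresholds: AssignmentThresholds | None = None):
    """Adjusted group label per the assignment rule; returns
    (label, boundary_flag)."""
    t = thresholds or AssignmentThresholds()
    q = np.asarray(q_row, dtype=float)
    order = np.argsort(-q, kind="stable")
    a, b = order[0], order[1]
    qa, qb = q[a], q[b]
    diff = qa - qb
    boundary = bool(qa > t.q_major and np.isclose(diff, t.delta_clear))
    if qa > t.q_major and (diff > t.delta_clear or boundary):
        return labels[a], boundary
    if (qa > t.q_major and diff < t.delta_clear) or \
            (qa <= t.q_major and diff >= t.delta_para):
        return f"{labels[a]}_Para", boundary
    return "Mixed", boundary


def assign_panel(Q: np.ndarray, labels, line_names=None,
                 thresholds: AssignmentThresholds | None = None
                 ) -> pd.DataFrame:
    """Per-line assignment table: Q values, default and adjusted IDs."""
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    names = list(line_names) if line_names is not None \
        else [f"line{i}" for i in range(n)]
    rows = []
    for i in range(n):
        q = Q[i]
        dlab, tie = default_id(q, labels)
        alab, boundary = adjusted_id(q, labels, thresholds)
        order = np.argsort(-q, kind="stable")
        rows.append({
            "line_name": names[i],
            **{f"Q_{lab}": q[k] for k, lab in enumerate(labels)},
            "default_id": dlab, "default_tie": tie,
            "adjusted_id": alab, "boundary": boundary,
            "q_max": q[order[0]], "q_second": q[order[1]],
            "group_of_max": labels[order[0]],
            "group_of_second": labels[order[1]],
        })
    return pd.DataFrame(rows)


def base_group(adjusted: str) -> str | None:
    """Strip the _Para suffix; Mixed has no base group."""
    if adjusted == "Mixed":
        return None
    return adjusted[:-5] if adjusted.endswith("_Para") else adjusted


def indicator_concordance(assignments: pd.DataFrame,
                          registry: LineRegistry):
    """Concordance of adjusted IDs with known indicator-line groups.

    A line is concordant when the base group of its adjusted ID (Para
    stripped) equals its known group; Mixed counts discordant.  Returns
    (fraction, per-line table).
    """
    known = registry.table.dropna(subset=["known_group"])
    if known.empty:
        raise ValueError("no indicator lines with a known group")
    merged = known.merge(assignments, on="line_name", how="inner")
    if merged.empty:
        raise ValueError("no indicator lines present in the assignments")
    merged = merged.assign(
        assigned_base=[base_group(a) for a in merged["adjusted_id"]])
    merged["concordant"] = merged["assigned_base"] == merged["known_group"]
    cols = ["line_name", "known_group", "default_id", "adjusted_id",
            "assigned_base", "concordant", "q_max"]
    return float(merged["concordant"].mean()), merged[cols]


def group_shares(assignments: pd.DataFrame,
                 grouping_map: dict | None = None) -> pd.DataFrame:
    """Proportion of lines per group under two conventions.

    mode "with_para": Para lines count with their base group, Mixed stands
    alone; mode "adjusted": the adjusted labels verbatim.  An optional
    grouping_map rolls groups up into supergroups (mode "supergroup").
    Proportions within each mode sum to 1.
    """
    n = len(assignments)
    rows = []

    def tally(mode, series):
        counts = series.value_counts()
        for lab, cnt in counts.items():
            rows.append({"mode": mode, "group": lab, "n": int(cnt),
                         "proportion": cnt / n})

    tally("adjusted", assignments["adjusted_id"])
    tally("with_para", assignments["adjusted_id"].map(
        lambda a: base_group(a) or "Mixed"))
    if grouping_map is not None:
        tally("supergroup", assignments["adjusted_id"].map(
            lambda a: grouping_map.get(base_group(a), "Mixed")))
    return pd.DataFrame(rows)
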