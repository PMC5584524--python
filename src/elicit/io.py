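"""Panel CSV interchange.

A panel file has one row per expert with the fixed columns
``expert_id, arm, L, M, H, p1, p2, p3, p4`` — the interval probabilities in
percent — and a sidecar JSON file carrying the quantity metadata
(:class:`~elicit.quantities.QuantityDefinition`).  L/M/H are written on the
quantity scale by default; ``values="normalized"`` reads/writes them on the
unit interval instead, for tools that pre-normalize.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .hybrid import HybridSummaries, probabilities_from_percent
from .quantities import EncodingError, QuantityDefinition

PANEL_COLUMNS = ["expert_id", "arm", "L", "M", "H", "p1", "p2", "p3", "p4"]


def write_panel_csv(
    path: str | Path,
    panel: list[HybridSummaries],
    quantity: QuantityDefinition,
    expert_ids=None,
    arms=None,
    values: str = "quantity",
) -> None:
    """Write a panel to CSV with a ``<path>.quantity.json`` sidecar."""
    if values not in ("quantity", "normalized"):
        raise ValueError(f"values must be 'quantity' or 'normalized', got {values!r}")
    n = len(panel)
    expert_ids = list(expert_ids) if expert_ids is not None else list(range(1, n + 1))
    arms = list(arms) if arms is not None else [""] * n
    rows = []
    for eid, arm, s in zip(expert_ids, arms, panel):
        if values == "normalized":
            s = s.normalized(quantity)
        rows.append(
            {
                "expert_id": eid,
                "arm": arm,
                "L": s.L,
                "M": s.M,
                "H": s.H,
                **{f"p{i + 1}": round(100.0 * s.p[i], 9) for i in range(4)},
            }
        )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)
    quantity.save(sidecar_path(path))


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".quantity.json")


def read_panel_csv(
    path: str | Path,
    quantity: QuantityDefinition | None = None,
    values: str = "quantity",
):
    """Read a panel CSV.

    Returns ``(df, panel, quantity)`` where ``df`` is the raw frame, and
    ``panel`` is a list of :class:`HybridSummaries` on the quantity scale.
    The quantity comes from the sidecar JSON unless passed explicitly.
    """
    if values not in ("quantity", "normalized"):
        raise ValueError(f"values must be 'quantity' or 'normalized', got {values!r}")
    path = Path(path)
    if quantity is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise EncodingError(
                f"no quantity given and sidecar {sc.name} not found next to {path.name}"
            )
        quantity = QuantityDefinition.load(sc)
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns and c != "arm"]
    if missing:
        raise EncodingError(f"panel CSV is missing required columns: {missing}")
    if "arm" not in df.columns:
        df["arm"] = ""
    panel = []
    for _, row in df.iterrows():
        p = probabilities_from_percent([row[f"p{i + 1}"] for i in range(4)])
        s = HybridSummaries(L=float(row.L), M=float(row.M), H=float(row.H), p=p)
        if values == "normalized":
            # stored on [0, 1]: map back to the quantity scale
            s = HybridSummaries(
                L=quantity.from_normalized(s.L),
                M=quantity.from_normalized(s.M),
                H=quantity.from_normalized(s.H),
                p=s.p,
            )
        panel.append(s)
    return df, panel, quantity


def export_records_csv(records, path: str | Path) -> pd.DataFrame:
    """Flatten completed session records into a panel-style CSV.

    Columns: expert_id, L, M, H, p1..p4 (percent), vas, training_s,
    questionnaire_s.  Only records with a final main answer are exported.
    Returns the frame that was written.
    """
    rows = []
    for rec in records:
        s = rec.final_main_answer
        if s is None:
            continue
        rows.append(
            {
                "expert_id": rec.session_id,
                "L": s.L,
                "M": s.M,
                "H": s.H,
                **{f"p{i + 1}": round(100.0 * s.p[i], 9) for i in range(4)},
                "vas": rec.vas_certainty,
                "training_s": rec.timings.get("training"),
                "questionnaire_s": rec.timings.get("questionnaire"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["expert_id", "L", "M", "H", "p1", "p2", "p3", "p4",
                 "vas", "training_s", "questionnaire_s"],
    )
    df.to_csv(path, index=False)
    return df


def panel_to_dataframe(
    panel: list[HybridSummaries], expert_ids=None, arms=None
) -> pd.DataFrame:
    """The in-memory equivalent of the panel CSV (probabilities in percent)."""
    n = len(panel)
    expert_ids = list(expert_ids) if expert_ids is not None else list(range(1, n + 1))
    arms = list(arms) if arms is not None else [""] * n
    return pd.DataFrame(
        [
            {
                "expert_id": eid,
                "arm": arm,
                "L": s.L,
                "M": s.M,
                "H": s.H,
                **{f"p{i + 1}": round(100.0 * s.p[i], 9) for i in range(4)},
            }
            for eid, arm, s in zip(expert_ids, arms, panel)
        ],
        columns=PANEL_COLUMNS,
    )
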