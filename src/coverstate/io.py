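"""Reading cover-class panels from CSV and writing run outputs.

The interchange format is a long CSV with one row per recorded
(quadrat, occasion) observation::

    quadrat,occasion_label,cover_class
    1,1957,+
    2,1957,3

``quadrat`` indices must form a contiguous 1..N_Q range in spatial order
along the line of quadrats.  ``cover_class`` is either already the model's
1..K labels (``recode="identity"``) or field notation ``+,1,2,3,4,5``
(``recode="field6"``), which maps ``+`` -> 1 and shifts the numbered
classes up by one.  Cells absent from the file at surveyed occasions are
ambiguous — a species may be genuinely absent (non-detection, folded into
class 1) or simply unrecorded — so the caller must choose ``absent="class1"``
or ``absent="missing"`` explicitly; there is no default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .beta_ordinal import CutPoints
from .inference import DrawsTable, PosteriorDraws, summarize
from .model import MISSING, CoverPanel, TimeGrid
from .ppc import Rootogram

__all__ = ["PanelValidationError", "read_panel", "write_panel", "read_draws", "write_outputs"]

REQUIRED_COLUMNS = ("quadrat", "occasion_label", "cover_class")

_FIELD6 = {"+": 1, "1": 2, "2": 3, "3": 4, "4": 5, "5": 6}


class PanelValidationError(ValueError):
    """Malformed panel file; the message carries 1-based data row numbers."""


def _recode(values: pd.Series, rule: str, K: int) -> np.ndarray:
    labels = np.empty(len(values), dtype=np.int64)
    for pos, raw in enumerate(values.astype(str).str.strip()):
        if rule == "field6":
            if raw not in _FIELD6:
                raise PanelValidationError(
                    f"row {pos + 2}: unknown field class symbol {raw!r} "
                    f"(expected one of {sorted(_FIELD6)})")
            labels[pos] = _FIELD6[raw]
        elif rule == "identity":
            try:
                val = int(raw)
            except ValueError:
                raise PanelValidationError(
                    f"row {pos + 2}: cover_class {raw!r} is not an integer") from None
            if not (1 <= val <= K):
                raise PanelValidationError(
                    f"row {pos + 2}: cover_class {val} outside 1..{K}")
            labels[pos] = val
        else:
            raise ValueError(f"unknown recode rule {rule!r}; use 'identity' or 'field6'")
    return labels


def read_panel(
    path: str | Path,
    recode: str,
    absent: str,
    cuts: CutPoints | None = None,
) -> tuple[CoverPanel, TimeGrid]:
    """Load a panel CSV into a :class:`CoverPanel` plus its :class:`TimeGrid`.

    ``recode`` is ``"identity"`` or ``"field6"``; ``absent`` — how to treat
    (quadrat, occasion) cells missing from the file at surveyed occasions —
    is ``"class1"`` (non-detection folded into the lowest class) or
    ``"missing"``.  Both are mandatory.
    """
    if absent not in ("class1", "missing"):
        raise ValueError(f"absent must be 'class1' or 'missing'; got {absent!r}")
    if cuts is None:
        cuts = CutPoints.default()
    df = pd.read_csv(path, dtype={"quadrat": "Int64", "occasion_label": "Int64"})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"missing required columns: {missing_cols}")
    if df["quadrat"].isna().any() or df["occasion_label"].isna().any():
        bad = int(df.index[df["quadrat"].isna() | df["occasion_label"].isna()][0])
        raise PanelValidationError(f"row {bad + 2}: quadrat/occasion_label must be integers")

    labels = _recode(df["cover_class"], recode, cuts.K)

    dup = df.duplicated(subset=["quadrat", "occasion_label"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise PanelValidationError(f"duplicate (quadrat, occasion_label) cells at rows {rows}")

    quadrats = df["quadrat"].astype(np.int64).to_numpy()
    uniq_q = np.unique(quadrats)
    n_q = uniq_q.size
    if uniq_q[0] != 1 or uniq_q[-1] != n_q:
        raise PanelValidationError(
            f"quadrat indices must be contiguous 1..N_Q; found {uniq_q.tolist()[:10]}")

    occ_labels = df["occasion_label"].astype(np.int64).to_numpy()
    grid = TimeGrid.from_observed_labels(occ_labels)
    obs_steps = grid.observed_steps
    step_to_row = {int(s): i for i, s in enumerate(obs_steps)}

    fill = 1 if absent == "class1" else MISSING
    classes = np.full((obs_steps.size, n_q), fill, dtype=np.int64)
    for q, lab, y in zip(quadrats, occ_labels, labels):
        classes[step_to_row[grid.step_of(lab)], q - 1] = y

    panel = CoverPanel(classes=classes, occasions=obs_steps, cuts=cuts)
    return panel, grid


def write_panel(path: str | Path, panel: CoverPanel, grid: TimeGrid) -> None:
    """Write a panel as the long interchange CSV (missing cells omitted)."""
    rows = []
    labels = np.asarray(grid.labels)
    for o in range(panel.n_occasions):
        lab = labels[panel.occasions[o]]
        for q in range(panel.n_quadrats):
            y = panel.classes[o, q]
            if y != MISSING:
                rows.append((q + 1, int(lab), int(y)))
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def read_draws(path: str | Path) -> DrawsTable:
    """Read a long draws CSV back into a summarisable table."""
    df = pd.read_csv(path)
    arrays = {}
    for name, sub in df.groupby("parameter", sort=False):
        piv = sub.pivot(index="chain", columns="draw", values="value")
        arrays[str(name)] = piv.to_numpy()
    return DrawsTable(arrays)


def write_outputs(
    out_dir: str | Path,
    draws: PosteriorDraws | None = None,
    summaries: pd.DataFrame | None = None,
    rootograms: Iterable[Rootogram] | None = None,
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write draws, summary, rootogram tables and the run config to a directory.

    Returns the paths written.  The summary CSV mirrors the posterior-table
    columns (parameter, mean, p2.5, p50, p97.5, rhat); the config JSON
    records the seed for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if draws is not None:
        p = out / "draws.csv"
        draws.to_long_dataframe().to_csv(p, index=False)
        written["draws"] = p
    if summaries is not None:
        p = out / "summary.csv"
        summaries.to_csv(p, index=False)
        written["summary"] = p
    if rootograms is not None:
        frames = [rg.to_frame() for rg in rootograms]
        if frames:
            p = out / "rootograms.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            written["rootograms"] = p
    if config is not None:
        p = out / "run_config.json"
        with open(p, "w") as fh:
            json.dump(dict(config), fh, indent=2, sort_keys=True)
        written["config"] = p
    return written
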