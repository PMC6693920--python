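"""Trial-level data structures and CSV readers/writers.

Two decision tasks are supported, each in two CSV dialects:

``value`` trials (choices between two valued items)
    * ``exp1`` dialect, 8 columns: subject, rt, chose_right, value_left,
      value_right, item_left, item_right, response key (``#3``=left, ``$4``=right).
      Values are dollar willingness-to-pay on a $0-3 scale.
    * ``exp2`` dialect, 12 columns: subject, group, item_left, item_right,
      response key (``z``=left, ``m``=right), rt, rating_left, rating_right,
      chose_right, z_left, z_right, delta_value.  Values are within-subject
      z-scored ratings.

``perceptual`` trials (two-color discrimination)
    * ``exp1`` dialect, 7 columns: subject, coherence, p_blue, response key
      (``#3``=left, ``$4``=right), rt, button_order, chose_blue.
    * ``exp2`` dialect, 8 columns: adds a group column after subject and uses
      ``z``/``m`` response keys.

Readers normalize the raw response-key columns to canonical ``chose_right`` /
``chose_blue`` binaries (using ``button_order`` for the perceptual task) and
discard the key codes; writers regenerate them.  Rows with a missing response
(empty rt / choice cells) are retained with ``valid=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DialectError, ParseError

__all__ = [
    "ValueTrial",
    "PerceptualTrial",
    "TrialTable",
    "RatingTable",
    "read_value_trials",
    "write_value_trials",
    "read_perceptual_trials",
    "write_perceptual_trials",
    "zscore_ratings",
    "compute_delta_value",
]

Dialect = Literal["exp1", "exp2"]

#: default response deadlines (seconds) per task and dialect
DEADLINES = {
    ("value", "exp1"): 3.0,
    ("perceptual", "exp1"): 2.5,
    ("value", "exp2"): 3.5,
    ("perceptual", "exp2"): 3.5,
}

_VALUE_COLS = {
    "exp1": [
        "subject", "rt", "chose_right", "value_left", "value_right",
        "item_left", "item_right", "response",
    ],
    "exp2": [
        "subject", "group", "item_left", "item_right", "response", "rt",
        "rating_left", "rating_right", "chose_right", "z_left", "z_right",
        "delta_value",
    ],
}

_PERCEPTUAL_COLS = {
    "exp1": [
        "subject", "coherence", "p_blue", "response", "rt", "button_order",
        "chose_blue",
    ],
    "exp2": [
        "subject", "group", "coherence", "p_blue", "response", "rt",
        "button_order", "chose_blue",
    ],
}

_KEYS = {"exp1": ("#3", "$4"), "exp2": ("z", "m")}  # (left, right)


@dataclass
class ValueTrial:
    """One two-item value-based decision."""

    subject: str
    value_left: float
    value_right: float
    chose_right: int
    rt: float
    valid: bool = True
    group: str | None = None
    item_left: str | None = None
    item_right: str | None = None
    raw_left: float | None = None   # unstandardized rating (exp2 dialect)
    raw_right: float | None = None

    def __post_init__(self) -> None:
        if self.valid:
            if not self.rt > 0:
                raise ValueError(f"valid trial requires rt > 0, got {self.rt}")
            if self.chose_right not in (0, 1):
                raise ValueError("chose_right must be 0 or 1 on valid trials")

    @property
    def chosen_value(self) -> float:
        return self.value_right if self.chose_right else self.value_left

    @property
    def unchosen_value(self) -> float:
        return self.value_left if self.chose_right else self.value_right


@dataclass
class PerceptualTrial:
    """One color-discrimination decision.

    ``coherence`` is the signed log-odds that a dot is blue;
    ``p_blue = logistic(coherence)``.  ``button_order`` 1 means blue maps to
    the left response key, 2 means blue maps to the right key.
    """

    subject: str
    coherence: float
    p_blue: float
    chose_blue: int
    rt: float
    button_order: int = 1
    valid: bool = True
    group: str | None = None

    def __post_init__(self) -> None:
        if self.valid:
            if not self.rt > 0:
                raise ValueError(f"valid trial requires rt > 0, got {self.rt}")
            if self.chose_blue not in (0, 1):
                raise ValueError("chose_blue must be 0 or 1 on valid trials")
        if self.button_order not in (1, 2):
            raise ValueError("button_order must be 1 or 2")


@dataclass
class TrialTable:
    """Ordered, homogeneous collection of trials plus session metadata."""

    trials: list
    kind: Literal["value", "perceptual"]
    experiment: str = "exp1"
    deadline: float = 3.0
    group: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("value", "perceptual"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if not self.deadline > 0:
            raise ValueError("deadline must be positive")
        cls = ValueTrial if self.kind == "value" else PerceptualTrial
        for t in self.trials:
            if not isinstance(t, cls):
                raise TypeError(f"heterogeneous table: expected {cls.__name__}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator:
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def valid_trials(self) -> "TrialTable":
        return replace(self, trials=[t for t in self.trials if t.valid])

    def filter_group(self, label: str) -> "TrialTable":
        return replace(
            self,
            trials=[t for t in self.trials if t.group == label],
            group=label,
        )

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject, None)
        return list(seen)

    # --- array views used by the likelihood/statistics layers -------------
    def strengths(self, round_step: float | None = None) -> np.ndarray:
        """Signed stimulus strength per trial (delta-value or coherence)."""
        if self.kind == "value":
            return np.array(
                [compute_delta_value(t, round_to=round_step) for t in self.trials]
            )
        return np.array([t.coherence for t in self.trials])

    def choices(self) -> np.ndarray:
        """Canonical upper-bound choice per trial (right item / blue color)."""
        if self.kind == "value":
            return np.array([t.chose_right for t in self.trials], dtype=float)
        return np.array([t.chose_blue for t in self.trials], dtype=float)

    def rts(self) -> np.ndarray:
        return np.array([t.rt for t in self.trials], dtype=float)


@dataclass
class RatingTable:
    """Per-subject item ratings, optionally standardized within subject."""

    frame: pd.DataFrame  # columns: subject, item, rating[, z_rating]

    def __post_init__(self) -> None:
        missing = {"subject", "item", "rating"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"rating table missing columns {sorted(missing)}")


def zscore_ratings(ratings: RatingTable) -> RatingTable:
    """Standardize ratings within each subject (sample sd, ddof=1).

    Raises :class:`DegenerateInputError` for any subject whose ratings are
    constant (or fewer than two), rather than silently emitting zeros.
    """
    frame = ratings.frame.copy()
    z = np.empty(len(frame), dtype=float)
    for subject, idx in frame.groupby("subject").groups.items():
        vals = frame.loc[idx, "rating"].to_numpy(dtype=float)
        if len(vals) < 2 or np.ptp(vals) == 0:
            raise DegenerateInputError(
                f"subject {subject!r}: ratings are constant or too few to z-score"
            )
        z[frame.index.get_indexer(idx)] = (vals - vals.mean()) / vals.std(ddof=1)
    frame["z_rating"] = z
    return RatingTable(frame)


def compute_delta_value(trial: ValueTrial, round_to: float | None = None) -> float:
    """Signed value difference, right minus left.

    With ``round_to`` set (e.g. 0.1 for dollar-scale values) the difference is
    rounded to the nearest multiple of the step, half away from zero.
    """
    dv = trial.value_right - trial.value_left
    if round_to is not None:
        dv = math.copysign(math.floor(abs(dv) / round_to + 0.5) * round_to, dv)
    return dv


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_raw(path, n_cols: int, dialect: str, rt_col: int) -> pd.DataFrame:
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if raw.shape[1] != n_cols:
        raise DialectError(
            f"{path}: expected {n_cols} columns for dialect {dialect!r}, "
            f"found {raw.shape[1]}"
        )
    # optional header row: drop it when the rt cell is non-empty, non-numeric
    first_rt = str(raw.iloc[0, rt_col]).strip()
    if first_rt:
        try:
            float(first_rt)
        except ValueError:
            raw = raw.iloc[1:].reset_index(drop=True)
    return raw


def _parse_float(cell: str, row: int, what: str) -> float:
    cell = str(cell).strip()
    if not cell:
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {row}: non-numeric {what} {cell!r}") from None


def read_value_trials(path, dialect: Dialect = "exp1") -> TrialTable:
    """Read a value-task trial CSV in the ``exp1`` (8-col, dollar WTP) or
    ``exp2`` (12-col, z-scored rating) dialect."""
    cols = _VALUE_COLS[dialect]
    raw = _read_raw(path, len(cols), dialect, rt_col=cols.index("rt"))
    raw.columns = cols
    trials = []
    for i, row in raw.iterrows():
        rt = _parse_float(row["rt"], i, "rt")
        chose = _parse_float(row["chose_right"], i, "chose_right")
        valid = math.isfinite(rt) and math.isfinite(chose)
        if dialect == "exp1":
            vl = _parse_float(row["value_left"], i, "value_left")
            vr = _parse_float(row["value_right"], i, "value_right")
            raw_l = raw_r = None
            group = None
        else:
            vl = _parse_float(row["z_left"], i, "z_left")
            vr = _parse_float(row["z_right"], i, "z_right")
            raw_l = _parse_float(row["rating_left"], i, "rating_left")
            raw_r = _parse_float(row["rating_right"], i, "rating_right")
            group = str(row["group"]).strip()
        trials.append(
            ValueTrial(
                subject=str(row["subject"]).strip(),
                value_left=vl,
                value_right=vr,
                chose_right=int(chose) if valid else -1,
                rt=rt if valid else math.nan,
                valid=valid,
                group=group,
                item_left=str(row["item_left"]).strip() or None,
                item_right=str(row["item_right"]).strip() or None,
                raw_left=raw_l,
                raw_right=raw_r,
            )
        )
    return TrialTable(
        trials,
        kind="value",
        experiment=dialect,
        deadline=DEADLINES[("value", dialect)],
    )


def read_perceptual_trials(path, dialect: Dialect = "exp1") -> TrialTable:
    """Read a perceptual-task trial CSV (7 columns for ``exp1``, 8 for
    ``exp2`` which adds a group column).

    Emits a warning-level check that ``p_blue`` is consistent with the
    logistic of coherence.
    """
    import warnings

    cols = _PERCEPTUAL_COLS[dialect]
    raw = _read_raw(path, len(cols), dialect, rt_col=cols.index("rt"))
    raw.columns = cols
    trials = []
    for i, row in raw.iterrows():
        rt = _parse_float(row["rt"], i, "rt")
        chose = _parse_float(row["chose_blue"], i, "chose_blue")
        coh = _parse_float(row["coherence"], i, "coherence")
        p_blue = _parse_float(row["p_blue"], i, "p_blue")
        if not math.isfinite(coh):
            raise ParseError(f"row {i}: missing coherence")
        expected = 1.0 / (1.0 + math.exp(-coh))
        if math.isfinite(p_blue) and abs(p_blue - expected) > 1e-6:
            warnings.warn(
                f"row {i}: p_blue {p_blue} inconsistent with coherence {coh}",
                stacklevel=2,
            )
        valid = math.isfinite(rt) and math.isfinite(chose)
        trials.append(
            PerceptualTrial(
                subject=str(row["subject"]).strip(),
                coherence=coh,
                p_blue=p_blue if math.isfinite(p_blue) else expected,
                chose_blue=int(chose) if valid else -1,
                rt=rt if valid else math.nan,
                button_order=int(_parse_float(row["button_order"], i, "button_order")),
                valid=valid,
                group=str(row["group"]).strip() if dialect == "exp2" else None,
            )
        )
    return TrialTable(
        trials,
        kind="perceptual",
        experiment=dialect,
        deadline=DEADLINES[("perceptual", dialect)],
    )


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return ""
    return repr(float(x))


def write_value_trials(table: TrialTable, path, header: bool = False) -> None:
    """Write a value-task table back to its CSV dialect (see module docs)."""
    if table.kind != "value":
        raise ValueError("write_value_trials requires a value table")
    dialect = table.experiment
    left_key, right_key = _KEYS[dialect]
    rows = []
    for t in table.trials:
        response = "" if not t.valid else (right_key if t.chose_right else left_key)
        chose = "" if not t.valid else str(int(t.chose_right))
        if dialect == "exp1":
            rows.append([
                t.subject, _fmt(t.rt), chose, _fmt(t.value_left),
                _fmt(t.value_right), t.item_left or "", t.item_right or "",
                response,
            ])
        else:
            rows.append([
                t.subject, t.group or "", t.item_left or "", t.item_right or "",
                response, _fmt(t.rt), _fmt(t.raw_left), _fmt(t.raw_right),
                chose, _fmt(t.value_left), _fmt(t.value_right),
                _fmt(t.value_right - t.value_left),
            ])
    frame = pd.DataFrame(rows, columns=_VALUE_COLS[dialect])
    frame.to_csv(path, index=False, header=header)


def write_perceptual_trials(table: TrialTable, path, header: bool = False) -> None:
    """Write a perceptual-task table back to its CSV dialect."""
    if table.kind != "perceptual":
        raise ValueError("write_perceptual_trials requires a perceptual table")
    dialect = table.experiment
    left_key, right_key = _KEYS[dialect]
    rows = []
    for t in table.trials:
        if t.valid:
            # button_order 1: blue is the left key
            chose_left = t.chose_blue == (1 if t.button_order == 1 else 0)
            response = left_key if chose_left else right_key
            chose = str(int(t.chose_blue))
        else:
            response = chose = ""
        base = [
            _fmt(t.coherence), _fmt(t.p_blue), response, _fmt(t.rt),
            str(t.button_order), chose,
        ]
        if dialect == "exp1":
            rows.append([t.subject] + base)
        else:
            rows.append([t.subject, t.group or ""] + base)
    frame = pd.DataFrame(rows, columns=_PERCEPTUAL_COLS[dialect])
    frame.to_csv(path, index=False, header=header)
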