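"""Trial-level data containers and delimited-text I/O.

Continuous-report CSV layout (header mandatory), one row per trial::

    condition, resp_x, resp_y, targ_x, targ_y,
    nt1_x, nt1_y, nt1_class, nt2_x, nt2_y, nt2_class, ...

Blank nontarget cells mean the item was absent on that trial, so the number
of nontargets may vary across rows.  Change-detection files replace the
response columns with ``probe_x, probe_y`` and a binary ``response`` column
(1 = judged "changed"/rejected, 0 = accepted as unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = ["TrialDataset", "CircularDataset", "ChangeDataset", "read_trials", "read_change_trials"]


def _pad_nontargets(nontargets: Sequence[np.ndarray]) -> np.ndarray:
    """Stack variable-length per-trial nontarget lists into a NaN-padded array."""
    n = len(nontargets)
    mmax = max((len(nt) for nt in nontargets), default=0)
    out = np.full((n, mmax, 2), np.nan)
    for i, nt in enumerate(nontargets):
        if len(nt):
            out[i, : len(nt)] = np.asarray(nt, dtype=float)
    return out


@dataclass
class TrialDataset:
    """Continuous-report trials for one participant/session.

    Attributes
    ----------
    responses, targets : (n, 2) float arrays
    nontargets : (n, m_max, 2) float array, NaN-padded
    nt_class : (n, m_max) int array; 0 marks padding/unlabelled
    condition : (n,) object array of labels (may be empty strings)
    screen : ScreenGeometry
    """

    responses: np.ndarray
    targets: np.ndarray
    nontargets: np.ndarray
    screen: ScreenGeometry
    nt_class: np.ndarray | None = None
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        nt = np.asarray(self.nontargets, dtype=float)
        if nt.size == 0:
            nt = np.empty((len(self), 0, 2))
        self.nontargets = nt
        if self.nt_class is None:
            self.nt_class = np.where(self.nontarget_mask, 1, 0)
        self.nt_class = np.asarray(self.nt_class, dtype=int)
        if self.condition is None:
            self.condition = np.array([""] * len(self), dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        n = len(self)
        if not (self.targets.shape[0] == n and self.nontargets.shape[0] == n):
            raise ValueError("inconsistent trial counts across fields")

    def __len__(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self)

    @property
    def nontarget_mask(self) -> np.ndarray:
        return np.isfinite(self.nontargets).all(axis=-1)

    @property
    def n_nontargets(self) -> np.ndarray:
        """Per-trial nontarget count m (may vary across trials)."""
        return self.nontarget_mask.sum(axis=1)

    def subset(self, idx) -> "TrialDataset":
        idx = np.asarray(idx)
        return TrialDataset(
            self.responses[idx],
            self.targets[idx],
            self.nontargets[idx],
            self.screen,
            nt_class=self.nt_class[idx],
            condition=self.condition[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "condition": self.condition,
            "resp_x": self.responses[:, 0],
            "resp_y": self.responses[:, 1],
            "targ_x": self.targets[:, 0],
            "targ_y": self.targets[:, 1],
        }
        mask = self.nontarget_mask
        for j in range(self.nontargets.shape[1]):
            cols[f"nt{j + 1}_x"] = np.where(mask[:, j], self.nontargets[:, j, 0], np.nan)
            cols[f"nt{j + 1}_y"] = np.where(mask[:, j], self.nontargets[:, j, 1], np.nan)
            cols[f"nt{j + 1}_class"] = np.where(mask[:, j], self.nt_class[:, j], np.nan)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, screen: ScreenGeometry) -> "TrialDataset":
        required = ["resp_x", "resp_y", "targ_x", "targ_y"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        if len(df) == 0:
            raise ValueError("file contains no data rows")
        resp = df[["resp_x", "resp_y"]].to_numpy(dtype=float)
        targ = df[["targ_x", "targ_y"]].to_numpy(dtype=float)
        if not np.isfinite(resp).all() or not np.isfinite(targ).all():
            bad = np.where(~(np.isfinite(resp).all(axis=1) & np.isfinite(targ).all(axis=1)))[0]
            raise ValueError(f"non-numeric response/target coordinates in rows {bad.tolist()}")
        j, nts, classes = 1, [], []
        while f"nt{j}_x" in df.columns:
            xy = df[[f"nt{j}_x", f"nt{j}_y"]].to_numpy(dtype=float)
            nts.append(xy)
            ccol = f"nt{j}_class"
            if ccol in df.columns:
                classes.append(pd.to_numeric(df[ccol], errors="coerce").to_numpy())
            else:
                classes.append(np.where(np.isfinite(xy).all(axis=1), 1.0, np.nan))
            j += 1
        if nts:
            nt = np.stack(nts, axis=1)
            cls = np.nan_to_num(np.stack(classes, axis=1), nan=0.0).astype(int)
        else:
            nt = np.empty((len(df), 0, 2))
            cls = np.zeros((len(df), 0), dtype=int)
        cond = (
            df["condition"].astype(object).to_numpy()
            if "condition" in df.columns
            else None
        )
        dataset = TrialDataset(resp, targ, nt, screen, nt_class=cls, condition=cond)
        pts = np.concatenate(
            [resp[:, None, :], targ[:, None, :], nt.reshape(len(df), -1, 2)], axis=1
        )
        ok = np.where(np.isfinite(pts).all(axis=-1), screen.contains(pts), True).all(axis=1)
        if not ok.all():
            bad = np.where(~ok)[0]
            raise ValueError(
                f"coordinates outside the {screen.width:g}x{screen.height:g} screen "
                f"in rows {bad.tolist()}"
            )
        return dataset


def read_trials(path, screen: ScreenGeometry) -> TrialDataset:
    """Read and validate a continuous-report trial CSV."""
    return TrialDataset.from_dataframe(pd.read_csv(path, float_precision="round_trip"), screen)


@dataclass
class CircularDataset:
    """1D (orientation) analogue: angles in radians, reduced to [-pi, pi)."""

    responses: np.ndarray
    targets: np.ndarray
    nontargets: np.ndarray  # (n, m_max), NaN-padded

    def __post_init__(self) -> None:
        from .components import wrap_angle

        self.responses = wrap_angle(np.atleast_1d(self.responses))
        self.targets = wrap_angle(np.atleast_1d(self.targets))
        nt = np.asarray(self.nontargets, dtype=float)
        if nt.size == 0:
            nt = np.empty((len(self.responses), 0))
        mask = np.isfinite(nt)
        from .components import wrap_angle as _w

        nt = np.where(mask, _w(np.where(mask, nt, 0.0)), np.nan)
        self.nontargets = nt

    def __len__(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self)

    def subset(self, idx) -> "CircularDataset":
        idx = np.asarray(idx)
        return CircularDataset(self.responses[idx], self.targets[idx], self.nontargets[idx])


@dataclass
class ChangeDataset:
    """2AFC change-detection trials.

    ``responses`` are binary: 1 = rejected as changed, 0 = accepted as
    unchanged.  Each probe must be displaced from its target (d > 0).
    """

    targets: np.ndarray
    probes: np.ndarray
    nontargets: np.ndarray
    responses: np.ndarray
    screen: ScreenGeometry
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        self.probes = np.atleast_2d(np.asarray(self.probes, dtype=float))
        nt = np.asarray(self.nontargets, dtype=float)
        if nt.size == 0:
            nt = np.empty((len(self), 0, 2))
        self.nontargets = nt
        self.responses = np.asarray(self.responses, dtype=int)
        if self.condition is None:
            self.condition = np.array([""] * len(self), dtype=object)
        if not set(np.unique(self.responses)) <= {0, 1}:
            raise ValueError("responses must be binary 0/1")
        if (self.displacements <= 0).any():
            raise ValueError("every probe must have displacement d > 0")

    def __len__(self) -> int:
        return self.targets.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self)

    @property
    def displacements(self) -> np.ndarray:
        return np.linalg.norm(self.probes - self.targets, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "condition": self.condition,
            "targ_x": self.targets[:, 0],
            "targ_y": self.targets[:, 1],
            "probe_x": self.probes[:, 0],
            "probe_y": self.probes[:, 1],
        }
        for j in range(self.nontargets.shape[1]):
            cols[f"nt{j + 1}_x"] = self.nontargets[:, j, 0]
            cols[f"nt{j + 1}_y"] = self.nontargets[:, j, 1]
        cols["response"] = self.responses
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_change_trials(path, screen: ScreenGeometry) -> ChangeDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["targ_x", "targ_y", "probe_x", "probe_y", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    if len(df) == 0:
        raise ValueError("file contains no data rows")
    j, nts = 1, []
    while f"nt{j}_x" in df.columns:
        nts.append(df[[f"nt{j}_x", f"nt{j}_y"]].to_numpy(dtype=float))
        j += 1
    nt = np.stack(nts, axis=1) if nts else np.empty((len(df), 0, 2))
    return ChangeDataset(
        df[["targ_x", "targ_y"]].to_numpy(dtype=float),
        df[["probe_x", "probe_y"]].to_numpy(dtype=float),
        nt,
        df["response"].to_numpy(dtype=int),
        screen,
        condition=df["condition"].astype(object).to_numpy() if "condition" in df.columns else None,
    )
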