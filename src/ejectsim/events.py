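"""Event series: the unit of analysis.

An :class:`EventSeries` is the ordered record of ``(t, m, s)`` transitions of
one ejection run — ``m`` monomers in the cavity, ``s`` in the semi-space,
``N = m + m_pore + s`` — appended whenever ``m`` or ``s`` changes. Both the
Langevin simulator and the synthetic fixtures emit this schema; the analysis
layer consumes it.

On disk a run is a CSV with header ``t,m,s`` plus a JSON sidecar of run
metadata (seed, parameters, censored flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EventSeries", "save_ensemble", "load_ensemble"]


@dataclass
class EventSeries:
    """Ordered (t, m, s) record of one run.

    Invariants (enforced by :meth:`validate`): t strictly increasing; m and s
    change by bounded integer steps between consecutive records; an
    uncensored, completed run ends at s = N.
    """

    t: np.ndarray
    m: np.ndarray
    s: np.ndarray
    N: int
    m_p: int
    seed: int | None = None
    censored: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.s = np.asarray(self.s, dtype=np.int64)
        if not (len(self.t) == len(self.m) == len(self.s)):
            raise ValueError("t, m, s must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def pore_count(self) -> np.ndarray:
        """Monomers inside the pore at each record, N - m - s."""
        return self.N - self.m - self.s

    @property
    def span(self) -> float:
        """Total recorded time, last minus first."""
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def validate(self, max_jump: int = 4) -> None:
        """Raise if a series invariant is violated."""
        if len(self.t) == 0:
            raise ValueError("empty event series")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times not strictly increasing")
        if np.any(np.abs(np.diff(self.m)) > max_jump) or np.any(
                np.abs(np.diff(self.s)) > max_jump):
            raise ValueError(f"state jump exceeds {max_jump} per record")
        pc = self.pore_count
        if np.any(pc < 0) or np.any(pc > self.N):
            raise ValueError("m + s exceeds N (bookkeeping broken)")
        if np.any(self.m < 0) or np.any(self.s < -self.m_p):
            raise ValueError("state counts out of range")
        if not self.censored:
            if self.m[-1] != 0 or self.s[-1] != self.N:
                raise ValueError(
                    f"uncensored run must end at (m=0, s=N), got "
                    f"(m={self.m[-1]}, s={self.s[-1]})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "m": self.m, "s": self.s})

    def save(self, path: str | Path) -> None:
        """Write `<path>.csv` (t,m,s) and `<path>.json` (metadata)."""
        path = Path(path)
        self.to_frame().to_csv(path.with_suffix(".csv"), index=False)
        side = {"N": int(self.N), "m_p": int(self.m_p),
                "seed": self.seed, "censored": bool(self.censored),
                "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EventSeries":
        path = Path(path)
        df = pd.read_csv(path.with_suffix(".csv"))
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(t=df["t"].to_numpy(), m=df["m"].to_numpy(), s=df["s"].to_numpy(),
                   N=side["N"], m_p=side["m_p"], seed=side.get("seed"),
                   censored=side.get("censored", False), meta=side.get("meta", {}))


def save_ensemble(runs: list[EventSeries], out_dir: str | Path,
                  prefix: str = "run") -> list[Path]:
    """Write one CSV/JSON pair per run into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, ev in enumerate(runs):
        p = out / f"{prefix}{i:04d}"
        ev.save(p)
        paths.append(p)
    return paths


def load_ensemble(run_dir: str | Path) -> list[EventSeries]:
    """Load every `*.csv` + sidecar pair from a directory, sorted by name."""
    run_dir = Path(run_dir)
    runs = []
    for csv in sorted(run_dir.glob("*.csv")):
        if csv.with_suffix(".json").exists():
            runs.append(EventSeries.load(csv.with_suffix("")))
    if not runs:
        raise FileNotFoundError(f"no event-series runs found in {run_dir}")
    return runs
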