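"""Age-grouped incidence tables (registry-style) and their text format.

A table is a sequence of non-overlapping, sorted, half-open age bins
[age_lo, age_hi) with a mean incidence per 100,000 person-years each, the
shape in which brain-tumour registries (CBTRUS) publish demographic data.
The final bin may be open-ended ("85+"), in which case it is closed at the
simulation horizon when the table is compared with model curves.

The on-disk dialect is comma-separated text with header
``age_lo,age_hi,rate_per_100k_py``, '.' decimals, optional '#' comment
lines, and a trailing '+' marking the open-ended final bin.  No registry
data is bundled; readers accept user-supplied tables and all tests run on
synthetic ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IncidenceTable", "read_incidence_table", "write_incidence_table"]

HEADER = ("age_lo", "age_hi", "rate_per_100k_py")


@dataclass(frozen=True)
class IncidenceTable:
    """Age-binned observed incidence rates.

    ``age_hi`` stores ``inf`` for an open-ended final bin (flagged by
    ``open_ended``); :meth:`closed_edges` materialises the finite upper
    edge at a given horizon.
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    rate: np.ndarray
    source: str = ""
    open_ended: bool = False

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lo, dtype=float)
        hi = np.asarray(self.age_hi, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "age_hi", hi)
        object.__setattr__(self, "rate", rate)
        if not (lo.shape == hi.shape == rate.shape) or lo.ndim != 1 or lo.size == 0:
            raise ValueError("age_lo, age_hi, rate must be equal-length 1-D arrays")
        self._validate()

    def _validate(self) -> None:
        lo, hi, rate = self.age_lo, self.age_hi, self.rate
        for i in range(lo.size):
            row = i + 1
            if not np.isfinite(lo[i]) or lo[i] < 0:
                raise ValueError(f"row {row}: age_lo must be finite and >= 0")
            if np.isinf(hi[i]) and not (self.open_ended and i == lo.size - 1):
                raise ValueError(
                    f"row {row}: only the final bin may be open-ended"
                )
            if not lo[i] < hi[i]:
                raise ValueError(f"row {row}: require age_lo < age_hi")
            if not np.isfinite(rate[i]) or rate[i] < 0:
                raise ValueError(f"row {row}: rate must be finite and >= 0")
            if i > 0:
                if lo[i] < lo[i - 1]:
                    raise ValueError(f"row {row}: bins must be sorted by age_lo")
                if lo[i] < hi[i - 1]:
                    raise ValueError(
                        f"row {row}: bin [{lo[i]:g}, {hi[i]:g}) overlaps "
                        f"previous bin [{lo[i-1]:g}, {hi[i-1]:g})"
                    )
        if self.open_ended and not np.isinf(hi[-1]):
            raise ValueError("open_ended is set but the final bin has a finite edge")

    def __len__(self) -> int:
        return int(self.age_lo.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceTable):
            return NotImplemented
        return (
            np.array_equal(self.age_lo, other.age_lo)
            and np.array_equal(self.age_hi, other.age_hi)
            and np.array_equal(self.rate, other.rate)
            and self.source == other.source
            and self.open_ended == other.open_ended
        )

    def closed_edges(self, t_max: float) -> tuple[np.ndarray, np.ndarray]:
        """(age_lo, age_hi) with an open-ended final bin closed at t_max."""
        hi = self.age_hi.copy()
        if self.open_ended:
            if t_max <= self.age_lo[-1]:
                raise ValueError(
                    f"t_max = {t_max:g} does not close the open-ended final bin "
                    f"starting at {self.age_lo[-1]:g}"
                )
            hi[-1] = t_max
        return self.age_lo.copy(), hi

    def widths(self, t_max: float) -> np.ndarray:
        lo, hi = self.closed_edges(t_max)
        return hi - lo

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_lo": self.age_lo, "age_hi": self.age_hi, "rate_per_100k_py": self.rate}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "") -> "IncidenceTable":
        """Build a table from a DataFrame with the standard three columns.

        ``age_hi`` entries may be numeric, ``inf``, or strings with a
        trailing '+' (registry style, final row only).
        """
        missing = [c for c in HEADER if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}; expected {HEADER}")
        hi_raw = list(df["age_hi"])
        hi = np.empty(len(hi_raw), dtype=float)
        open_ended = False
        for i, v in enumerate(hi_raw):
            row = i + 1
            text = str(v).strip()
            if text.endswith("+"):
                if i != len(hi_raw) - 1:
                    raise ValueError(f"row {row}: '+' is only valid in the final bin")
                hi[i] = np.inf
                open_ended = True
            else:
                try:
                    hi[i] = float(text)
                except ValueError as exc:
                    raise ValueError(f"row {row}: cannot parse age_hi {text!r}") from exc
                if np.isinf(hi[i]):
                    open_ended = open_ended or i == len(hi_raw) - 1
        try:
            lo = np.asarray(df["age_lo"], dtype=float)
            rate = np.asarray(df["rate_per_100k_py"], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric age_lo or rate column: {exc}") from exc
        return cls(age_lo=lo, age_hi=hi, rate=rate, source=source,
                   open_ended=bool(np.isinf(hi[-1])))


def read_incidence_table(path, source: str | None = None) -> IncidenceTable:
    """Read a table from delimited text; row-numbered validation errors."""
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:
        raise ValueError(f"cannot read incidence table {path!r}: {exc}") from exc
    if list(df.columns) != list(HEADER):
        raise ValueError(
            f"malformed header {list(df.columns)!r}; expected {list(HEADER)}"
        )
    df = df.astype({"age_lo": str, "age_hi": str, "rate_per_100k_py": str})
    try:
        lo = df["age_lo"].astype(float)
        rate = df["rate_per_100k_py"].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric value in table {path!r}: {exc}") from exc
    frame = pd.DataFrame(
        {"age_lo": lo, "age_hi": df["age_hi"], "rate_per_100k_py": rate}
    )
    return IncidenceTable.from_frame(frame, source=source if source is not None else str(path))


def write_incidence_table(table: IncidenceTable, path, header_comment: str | None = None) -> None:
    """Write a table in the standard dialect (open-ended bin as 'lo+')."""
    hi_text = [f"{v:.17g}" for v in table.age_hi]
    if table.open_ended:
        hi_text[-1] = f"{table.age_lo[-1]:.17g}+"
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(HEADER) + "\n")
        for lo, hi, rate in zip(table.age_lo, hi_text, table.rate):
            fh.write(f"{lo:.17g},{hi},{rate:.17g}\n")
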