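"""Event matrices, marker panels and delimited-matrix IO.

A CyTOF acquisition yields, per sample, an events x markers intensity
matrix (one row per cell, one column per antibody channel). This module
defines the in-memory container for such a matrix, the panel description
used to resolve channel names across cohorts with different antibody
panels, and plain-text readers/writers (one delimited file per sample,
header row = marker names).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EventMatrix", "PanelConfig", "read_events", "write_events"]

RAW = "raw"
ARCSINH = "arcsinh"


@dataclass
class EventMatrix:
    """Events x markers intensity matrix for a single sample.

    Parameters
    ----------
    values : ndarray of shape (n_events, n_markers)
        Intensities, raw ion counts or arcsinh-transformed.
    markers : list of str
        Column names, aligned with ``values``.
    sample_id : str
        Sample identifier.
    transform_state : {"raw", "arcsinh"}
        Whether ``values`` are on the raw or arcsinh scale.
    cofactor : float, optional
        Cofactor used by the arcsinh transform, recorded when applied.
    batch : str, optional
        Acquisition batch / cohort label.
    """

    values: np.ndarray
    markers: list[str]
    sample_id: str = "sample"
    transform_state: str = RAW
    cofactor: float | None = None
    batch: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x markers array")
        if self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"marker count mismatch: {self.values.shape[1]} columns vs "
                f"{len(self.markers)} marker names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event matrix contains non-finite values")
        if self.transform_state not in (RAW, ARCSINH):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def select_markers(self, markers: list[str]) -> "EventMatrix":
        """Return a copy restricted to ``markers`` (in the given order)."""
        missing = [m for m in markers if m not in self.markers]
        if missing:
            raise KeyError(f"markers not present in sample {self.sample_id}: {missing}")
        idx = [self.markers.index(m) for m in markers]
        return replace(self, values=self.values[:, idx], markers=list(markers))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.markers)


@dataclass
class PanelConfig:
    """Antibody panel description with cross-panel aliases.

    ``aliases`` maps alternative channel spellings (e.g. ``"PD1"``) to the
    canonical marker name used in this panel (``"PD-1"``). Technical
    channels (DNA intercalators, beads, viability) are dropped on read.
    """

    markers: list[str]
    technical_channels: list[str] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)
    name: str = "panel"

    def __post_init__(self) -> None:
        targets: dict[str, str] = {}
        for alias, target in self.aliases.items():
            key = alias.lower()
            if key in targets and targets[key] != target:
                raise ValueError(f"alias {alias!r} maps to more than one marker")
            targets[key] = target
        if len(set(m.lower() for m in self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names in panel")

    def resolve(self, channel: str) -> str | None:
        """Map a file channel name to a canonical marker, or None."""
        low = channel.lower()
        for m in self.markers:
            if m.lower() == low:
                return m
        target = self.aliases.get(channel, None)
        if target is None:
            for alias, t in self.aliases.items():
                if alias.lower() == low:
                    target = t
                    break
        if target is not None and target in self.markers:
            return target
        return None

    def is_technical(self, channel: str) -> bool:
        return channel.lower() in {c.lower() for c in self.technical_channels}


def read_events(
    path: str | Path,
    panel: PanelConfig,
    sample_id: str | None = None,
    transform_state: str = RAW,
) -> EventMatrix:
    """Read a delimited events x channels matrix restricted to a panel.

    Channel order in the file is irrelevant; channels are matched to panel
    markers by name or alias (case-insensitive), technical channels are
    dropped, and the output columns follow the panel's marker order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty event file")

    resolved: dict[str, str] = {}
    for col in df.columns:
        if panel.is_technical(col):
            continue
        target = panel.resolve(str(col))
        if target is not None:
            resolved[target] = col
    missing = [m for m in panel.markers if m not in resolved]
    if missing:
        raise KeyError(f"{path}: unresolvable panel markers {missing}")

    sub = df[[resolved[m] for m in panel.markers]]
    try:
        values = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        # locate the offending cell for the error message
        for j, col in enumerate(sub.columns):
            coerced = pd.to_numeric(sub[col], errors="coerce")
            bad = coerced.index[coerced.isna() & sub[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value at row {bad[0]}, column {col!r}"
                ) from exc
        raise
    return EventMatrix(
        values=values,
        markers=list(panel.markers),
        sample_id=sample_id or path.stem,
        transform_state=transform_state,
    )


def write_events(matrix: EventMatrix, path: str | Path) -> Path:
    """Write an event matrix as a delimited file (header = marker names)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    buf = _io.StringIO()
    matrix.to_frame().to_csv(buf, sep=sep, index=False, float_format="%.8g")
    path.write_text(buf.getvalue())
    return path
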