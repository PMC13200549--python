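"""Domain types for spectra and reading/writing/preprocessing of peak lists.

A *peak* is one spectral signal: a point in a D-dimensional coordinate space
(ppm per NMR axis, Th for m/z, seconds for retention time) carrying a
nonnegative intensity and, optionally, a class label (peptide id, cluster id,
amino-acid group).  A *spectrum* is an ordered collection of peaks sharing
dimensionality and axis metadata.  Spectra are treated as discrete measures:
alignment operates on normalized intensities, so preprocessing (noise
thresholding, normalization, per-axis rescaling) lives here, next to the I/O.

All operations are pure: they return new :class:`Spectrum` objects and never
mutate their inputs.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Peak",
    "Spectrum",
    "AxisScaling",
    "read_peaklist",
    "write_peaklist",
    "threshold_noise",
    "normalize_spectrum",
    "scale_axes",
]

#: column names recognized as metadata rather than coordinates
_META_COLUMNS = ("id", "label", "intensity")


@dataclass(frozen=True)
class Peak:
    """One spectral signal: position vector, intensity, optional label."""

    id: str
    position: np.ndarray
    intensity: float
    label: Optional[str] = None


@dataclass(frozen=True)
class Spectrum:
    """A collection of peaks sharing dimensionality and axis metadata.

    Parameters
    ----------
    positions:
        Array of shape ``(n_peaks, dim)`` with one coordinate per axis.
    intensities:
        Array of shape ``(n_peaks,)``.
    ids:
        Unique, stable peak identifiers (order matches ``positions`` rows).
    axes:
        One descriptor per axis, e.g. ``("mz", "rt")`` or ``("1H", "15N")``.
    labels:
        Optional per-peak class annotations.
    """

    positions: np.ndarray
    intensities: np.ndarray
    ids: tuple[str, ...]
    axes: tuple[str, ...]
    labels: Optional[tuple[Optional[str], ...]] = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, len(self.axes))
        inten = np.asarray(self.intensities, dtype=float).reshape(-1)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "axes", tuple(self.axes))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
        if pos.ndim != 2:
            raise ValueError("positions must be a 2-D array")
        n, d = pos.shape
        if d != len(self.axes):
            raise ValueError(
                f"positions have {d} coordinates but {len(self.axes)} axes declared"
            )
        if d < 1:
            raise ValueError("a spectrum needs at least one axis")
        if inten.shape != (n,):
            raise ValueError("intensities length does not match number of peaks")
        if len(self.ids) != n:
            raise ValueError("ids length does not match number of peaks")
        if len(set(self.ids)) != n:
            raise ValueError("peak ids must be unique within a spectrum")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of peaks")
        if not np.all(np.isfinite(pos)):
            raise ValueError("peak positions must be finite")

    # -- derived ---------------------------------------------------------
    @property
    def dim(self) -> int:
        return len(self.axes)

    @property
    def n_peaks(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n_peaks

    @property
    def total_intensity(self) -> float:
        """Sum of peak intensities, recomputed on access."""
        return float(self.intensities.sum()) if self.n_peaks else 0.0

    def __iter__(self) -> Iterator[Peak]:
        labels = self.labels or (None,) * self.n_peaks
        for i in range(self.n_peaks):
            yield Peak(self.ids[i], self.positions[i].copy(),
                       float(self.intensities[i]), labels[i])

    def label_of(self, peak_id: str) -> Optional[str]:
        if self.labels is None:
            return None
        return self.labels[self.index_of(peak_id)]

    def index_of(self, peak_id: str) -> int:
        try:
            return self._id_index[peak_id]
        except AttributeError:
            object.__setattr__(
                self, "_id_index", {pid: i for i, pid in enumerate(self.ids)}
            )
            return self._id_index[peak_id]

    def position_of(self, peak_id: str) -> np.ndarray:
        return self.positions[self.index_of(peak_id)]

    def replace(self, **kwargs) -> "Spectrum":
        data = dict(
            positions=self.positions,
            intensities=self.intensities,
            ids=self.ids,
            axes=self.axes,
            labels=self.labels,
        )
        data.update(kwargs)
        return Spectrum(**data)

    @classmethod
    def from_peaks(cls, peaks: Sequence[Peak], axes: Sequence[str]) -> "Spectrum":
        if peaks:
            positions = np.array([p.position for p in peaks], dtype=float)
        else:
            positions = np.empty((0, len(axes)))
        labels = [p.label for p in peaks]
        return cls(
            positions=positions,
            intensities=np.array([p.intensity for p in peaks], dtype=float),
            ids=tuple(p.id for p in peaks),
            axes=tuple(axes),
            labels=tuple(labels) if any(l is not None for l in labels) else None,
        )

    @classmethod
    def empty(cls, axes: Sequence[str]) -> "Spectrum":
        return cls(
            positions=np.empty((0, len(axes))),
            intensities=np.empty(0),
            ids=(),
            axes=tuple(axes),
        )


@dataclass(frozen=True)
class AxisScaling:
    """Per-axis dimensionless multipliers applied to peak coordinates.

    Used to make shifts on axes with different natural scales comparable
    before computing transport distances (e.g. compressing a nitrogen
    chemical-shift axis by 0.1 relative to the proton axis, or blowing up
    the m/z axis relative to retention time).
    """

    factors: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(float(f) for f in self.factors))
        if any(f <= 0 for f in self.factors):
            raise ValueError("all scaling factors must be strictly positive")

    @property
    def dim(self) -> int:
        return len(self.factors)

    def inverse(self) -> "AxisScaling":
        return AxisScaling(tuple(1.0 / f for f in self.factors))

    @classmethod
    def identity(cls, dim: int) -> "AxisScaling":
        return cls((1.0,) * dim)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_peaklist(path, format: Optional[str] = None,
                  dim: Optional[int] = None) -> Spectrum:
    """Read a peak list from TSV/CSV or an OpenMS featureXML file.

    Tabular dialect: a header row is required; the coordinate columns are
    every column that is neither named ``intensity`` nor one of the
    recognized metadata columns ``id`` / ``label``, taken in file order.
    If no ``intensity`` column is present every peak gets unit intensity
    (peak lists derived from assignment tables carry no intensities).

    Parameters
    ----------
    path:
        File path or file-like object.
    format:
        One of ``tsv``, ``csv``, ``featurexml``; inferred from the file
        suffix when omitted.
    dim:
        Expected dimensionality; validated when given.
    """
    fmt = format or _infer_format(path)
    if fmt == "featurexml":
        spectrum = _read_featurexml(path)
    elif fmt in ("tsv", "csv"):
        spectrum = _read_table(path, sep="\t" if fmt == "tsv" else ",")
    else:
        raise ValueError(f"unknown peak-list format: {fmt!r}")
    if dim is not None:
        if dim < 1:
            raise ValueError("dim must be a positive integer")
        if spectrum.dim != dim:
            raise ValueError(
                f"expected {dim}-dimensional peak list, file has {spectrum.dim} axes"
            )
    return spectrum


def _infer_format(path) -> str:
    name = path.name if hasattr(path, "name") else os.fspath(path)
    suffix = str(name).lower()
    if suffix.endswith(".featurexml") or suffix.endswith(".xml"):
        return "featurexml"
    if suffix.endswith(".csv"):
        return "csv"
    return "tsv"


def _read_table(path, sep: str) -> Spectrum:
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = list(df.columns)
    lower = [c.lower() for c in cols]
    if "intensity" in lower:
        icol = cols[lower.index("intensity")]
        axis_cols = [c for c in cols[: cols.index(icol)]
                     if c.lower() not in _META_COLUMNS]
        intensities = pd.to_numeric(df[icol], errors="coerce").to_numpy(float)
    else:
        axis_cols = [c for c in cols if c.lower() not in _META_COLUMNS]
        intensities = np.ones(len(df))
    if not axis_cols:
        raise ValueError("no coordinate columns found before 'intensity'")

    positions = np.empty((len(df), len(axis_cols)))
    for k, c in enumerate(axis_cols):
        vals = pd.to_numeric(df[c], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(
                f"missing or non-numeric coordinate in column {c!r}, "
                f"data row {bad[0] + 1}"
            )
        positions[:, k] = vals

    bad = np.flatnonzero(~np.isfinite(intensities) | (intensities < 0))
    if bad.size:
        raise ValueError(
            f"invalid intensity (missing or negative) at data row {bad[0] + 1}"
        )

    id_col = next((c for c in cols if c.lower() == "id"), None)
    ids = (
        tuple(df[id_col].astype(str))
        if id_col is not None
        else tuple(str(i) for i in range(len(df)))
    )
    label_col = next((c for c in cols if c.lower() == "label"), None)
    labels = tuple(df[label_col].astype(str)) if label_col is not None else None
    return Spectrum(
        positions=positions,
        intensities=intensities,
        ids=ids,
        axes=tuple(axis_cols),
        labels=labels,
    )


def _read_featurexml(path) -> Spectrum:
    """Map each <feature> of an OpenMS feature map to one centroid peak.

    OpenMS stores position dim 0 = retention time (seconds) and dim 1 = m/z;
    flowalign orders LC-MS axes as (mz, rt).  Convex hulls are ignored: each
    feature is a single centroid point.
    """
    tree = etree.parse(path if hasattr(path, "read") else os.fspath(path))
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    rows, ids = [], []
    for k, feat in enumerate(root.iter(f"{ns}feature")):
        rt = mz = None
        for pos in feat.findall(f"{ns}position"):
            d = pos.get("dim")
            if d == "0":
                rt = float(pos.text)
            elif d == "1":
                mz = float(pos.text)
        inten_el = feat.find(f"{ns}intensity")
        if rt is None or mz is None or inten_el is None:
            raise ValueError(f"feature #{k} lacks position or intensity")
        inten = float(inten_el.text)
        if inten < 0:
            raise ValueError(f"feature #{k} has negative intensity")
        rows.append((mz, rt, inten))
        ids.append(feat.get("id") or str(k))
    if not rows:
        return Spectrum.empty(("mz", "rt"))
    arr = np.asarray(rows)
    return Spectrum(
        positions=arr[:, :2],
        intensities=arr[:, 2],
        ids=tuple(ids),
        axes=("mz", "rt"),
    )


def write_peaklist(s: Spectrum, path, sep: str = "\t") -> None:
    """Write a spectrum as a table: axis columns, intensity, id, [label]."""
    data = {axis: s.positions[:, k] for k, axis in enumerate(s.axes)}
    data["intensity"] = s.intensities
    data["id"] = list(s.ids)
    if s.labels is not None:
        data["label"] = list(s.labels)
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def to_tsv_string(s: Spectrum) -> str:
    buf = io.StringIO()
    write_peaklist(s, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def threshold_noise(s: Spectrum, fraction: float,
                    drop_nonpositive_first: bool = True) -> Spectrum:
    """Drop non-positive peaks, then keep those above a fraction of the max.

    The retained set is exactly the peaks with intensity strictly greater
    than ``fraction`` times the maximum intensity among the remaining
    positive peaks, mirroring the ">10 % of the maximum" convention used for
    noise suppression in processed NMR peak lists.  Idempotent at fixed
    ``fraction``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    mask = s.intensities > 0
    if drop_nonpositive_first:
        if not mask.any():
            return _subset(s, np.zeros(s.n_peaks, dtype=bool))
        ref = s.intensities[mask].max()
    else:
        ref = s.intensities.max() if s.n_peaks else 0.0
    keep = mask & (s.intensities > fraction * ref)
    return _subset(s, keep)


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Scale intensities so they sum to one; positions are untouched."""
    total = s.total_intensity
    if total <= 0:
        raise ValueError("cannot normalize a spectrum with zero total intensity")
    return s.replace(intensities=s.intensities / total)


def scale_axes(s: Spectrum, a: AxisScaling) -> Spectrum:
    """Multiply coordinate k of every peak by ``a.factors[k]``."""
    if a.dim != s.dim:
        raise ValueError(
            f"scaling has {a.dim} factors but spectrum has {s.dim} axes"
        )
    return s.replace(positions=s.positions * np.asarray(a.factors))


def _subset(s: Spectrum, mask: np.ndarray) -> Spectrum:
    labels = None
    if s.labels is not None:
        labels = tuple(l for l, m in zip(s.labels, mask) if m)
    return Spectrum(
        positions=s.positions[mask],
        intensities=s.intensities[mask],
        ids=tuple(i for i, m in zip(s.ids, mask) if m),
        axes=s.axes,
        labels=labels,
    )
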