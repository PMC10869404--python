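"""Containers and I/O for 1D SAXS profiles.

A scattering curve is the triplet (q, I(q), sigma) with q in nm^-1 and
intensity in arbitrary (relative) units, plus sample metadata (protein
concentration, salinity, chain length).  Files are the de-facto standard
3-column ASCII ``.dat`` with ``#`` comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "ScatteringCurve",
    "CurveSeries",
    "MalformedFileError",
    "read_dat",
    "write_dat",
    "log_rebin",
]


class MalformedFileError(ValueError):
    """Raised when a .dat file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata attached to a scattering curve.

    Parameters
    ----------
    protein_concentration : float or None
        Protein concentration C in mg/ml.
    salinity : float or None
        Total monovalent salt concentration Cs in mM.
    label : str
        Free-text identifier.
    n_residues : int or None
        Chain length N in residues.
    """

    protein_concentration: float | None = None
    salinity: float | None = None
    label: str = ""
    n_residues: int | None = None

    def __post_init__(self) -> None:
        if self.protein_concentration is not None and self.protein_concentration < 0:
            raise ValueError("protein_concentration must be >= 0 mg/ml")
        if self.salinity is not None and self.salinity < 0:
            raise ValueError("salinity must be >= 0 mM")
        if self.n_residues is not None and self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


@dataclass(frozen=True)
class ScatteringCurve:
    """One background-subtracted 1D SAXS profile with 1-sigma uncertainties.

    Invariants enforced on construction: q strictly increasing and positive,
    arrays of equal length, finite intensity.  ``sigma_is_synthetic`` marks
    curves whose uncertainty column was reconstructed as sqrt(I) because the
    source file had only two columns.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)
    sigma_is_synthetic: bool = False

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q must be a non-empty 1D array")
        if i.shape != q.shape or s.shape != q.shape:
            raise ValueError("intensity and sigma must match q in length")
        if not np.all(np.isfinite(q)) or not np.all(np.isfinite(i)):
            raise ValueError("q and intensity must be finite")
        if np.any(q <= 0):
            raise ValueError("all q must be > 0 (nm^-1)")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.q.size

    def select(self, mask: np.ndarray) -> "ScatteringCurve":
        """Return the sub-curve at the boolean ``mask``."""
        return replace(
            self, q=self.q[mask], intensity=self.intensity[mask], sigma=self.sigma[mask]
        )

    def scaled(self, factor: float) -> "ScatteringCurve":
        """Multiply intensity and sigma by a common factor."""
        return replace(
            self, intensity=self.intensity * factor, sigma=self.sigma * factor
        )


@dataclass(frozen=True)
class CurveSeries:
    """Ordered collection of curves varying along one metadata axis.

    ``axis`` is either ``"concentration"`` or ``"salinity"``; every curve
    must share the same value of the *other* field.
    """

    curves: tuple[ScatteringCurve, ...]
    axis: str = "concentration"

    def __post_init__(self) -> None:
        if self.axis not in ("concentration", "salinity"):
            raise ValueError("axis must be 'concentration' or 'salinity'")
        curves = tuple(self.curves)
        if len(curves) == 0:
            raise ValueError("series must contain at least one curve")
        fixed = "salinity" if self.axis == "concentration" else "protein_concentration"
        values = {getattr(c.meta, fixed) for c in curves}
        if len(values) > 1:
            raise ValueError(
                f"all curves in a {self.axis} series must share the same {fixed}; "
                f"got {sorted(v for v in values if v is not None)}"
            )
        object.__setattr__(self, "curves", curves)

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    @property
    def axis_values(self) -> np.ndarray:
        attr = (
            "protein_concentration" if self.axis == "concentration" else "salinity"
        )
        return np.array([getattr(c.meta, attr) for c in self.curves], dtype=float)


def _parse_meta_comment(line: str, meta_kw: dict) -> None:
    # recognise '# key: value' comments written by write_dat
    body = line.lstrip("#").strip()
    if ":" not in body:
        return
    key, _, value = body.partition(":")
    key = key.strip()
    value = value.strip()
    try:
        if key == "concentration_mg_ml":
            meta_kw["protein_concentration"] = float(value)
        elif key == "salinity_mM":
            meta_kw["salinity"] = float(value)
        elif key == "n_residues":
            meta_kw["n_residues"] = int(value)
        elif key == "label":
            meta_kw["label"] = value
    except ValueError:
        pass


def read_dat(
    path: str | Path,
    *,
    q_unit: str = "nm^-1",
    meta: SampleMeta | None = None,
) -> ScatteringCurve:
    """Read a 3-column ASCII SAXS curve (q, I, sigma).

    Comment lines start with ``#``.  A two-column file is accepted with the
    Poisson-like fallback sigma = sqrt(max(I, eps)), flagged in the returned
    curve so downstream fits can treat the weights as nominal.  ``q_unit``
    may be ``"nm^-1"`` (native) or ``"A^-1"``; the latter is converted by
    multiplying q by 10.  Rows are sorted into ascending q if needed.
    """
    path = Path(path)
    if q_unit not in ("nm^-1", "A^-1"):
        raise ValueError(f"unsupported q unit {q_unit!r}")
    rows: list[tuple[float, ...]] = []
    ncols: int | None = None
    meta_kw: dict = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_meta_comment(line, meta_kw)
                continue
            parts = line.split()
            if len(parts) < 2:
                raise MalformedFileError(
                    f"{path}: line {lineno}: expected >= 2 numeric columns, "
                    f"got {line!r}"
                )
            try:
                values = tuple(float(p) for p in parts[:3])
            except ValueError:
                raise MalformedFileError(
                    f"{path}: line {lineno}: non-numeric data {line!r}"
                ) from None
            if ncols is None:
                ncols = len(values)
            rows.append(values[: ncols if ncols is not None else 3])
    if not rows:
        raise MalformedFileError(f"{path}: no data rows found")
    arr = np.array([r[:2] for r in rows], dtype=float)
    q, intensity = arr[:, 0], arr[:, 1]
    has_sigma = all(len(r) >= 3 for r in rows)
    if has_sigma:
        sigma = np.array([r[2] for r in rows], dtype=float)
        synthetic = False
    else:
        sigma = np.sqrt(np.maximum(intensity, np.finfo(float).tiny))
        synthetic = True
        logger.warning(
            "%s: no uncertainty column; using sigma = sqrt(I) fallback", path
        )
    if q_unit == "A^-1":
        q = q * 10.0
    order = np.argsort(q)
    if not np.all(order == np.arange(q.size)):
        q, intensity, sigma = q[order], intensity[order], sigma[order]
    if meta is None:
        meta = SampleMeta(**meta_kw)
    return ScatteringCurve(
        q=q, intensity=intensity, sigma=sigma, meta=meta, sigma_is_synthetic=synthetic
    )


def write_dat(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3-column ASCII at full double precision.

    The round trip ``read_dat(write_dat(curve))`` reproduces q, I and sigma
    to better than 12 significant digits.  Sample metadata is stored in
    ``# key: value`` comments and recovered on read.
    """
    if len(curve) == 0:
        raise ValueError("refusing to write an empty curve")
    if not np.all(np.isfinite(curve.intensity)) or not np.all(
        np.isfinite(curve.sigma)
    ):
        raise ValueError("curve contains non-finite intensity or sigma")
    path = Path(path)
    m = curve.meta
    lines = ["# q[nm^-1]  I[arb]  sigma[arb]"]
    if m.label:
        lines.append(f"# label: {m.label}")
    if m.protein_concentration is not None:
        lines.append(f"# concentration_mg_ml: {m.protein_concentration!r}")
    if m.salinity is not None:
        lines.append(f"# salinity_mM: {m.salinity!r}")
    if m.n_residues is not None:
        lines.append(f"# n_residues: {m.n_residues}")
    for qi, ii, si in zip(curve.q, curve.intensity, curve.sigma):
        lines.append(f"{qi:.16e} {ii:.16e} {si:.16e}")
    path.write_text("\n".join(lines) + "\n")


def log_rebin(curve: ScatteringCurve, n_bins: int = 100) -> ScatteringCurve:
    """Rebin a curve onto geometric (logarithmic) q bins.

    Bin edges are geometrically spaced between min(q) and max(q).  Within a
    bin, q and I are inverse-variance (sigma^-2) weighted means and the bin
    sigma is the standard error of the weighted mean, 1/sqrt(sum w).  Empty
    bins are dropped.  The default of 100 bins matches common practice for
    reducing the cost of expensive form-factor fits.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    q, i, s = curve.q, curve.intensity, curve.sigma
    if np.any(s <= 0):
        raise ValueError("sigma must be > 0 for weighted rebinning")
    edges = np.geomspace(q[0], q[-1], n_bins + 1)
    # right-inclusive last bin so the final point is kept
    idx = np.clip(np.searchsorted(edges, q, side="right") - 1, 0, n_bins - 1)
    w = 1.0 / s**2
    sw = np.bincount(idx, weights=w, minlength=n_bins)
    occupied = sw > 0
    q_b = np.bincount(idx, weights=w * q, minlength=n_bins)[occupied] / sw[occupied]
    i_b = np.bincount(idx, weights=w * i, minlength=n_bins)[occupied] / sw[occupied]
    s_b = 1.0 / np.sqrt(sw[occupied])
    return ScatteringCurve(
        q=q_b,
        intensity=i_b,
        sigma=s_b,
        meta=curve.meta,
        sigma_is_synthetic=curve.sigma_is_synthetic,
    )
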