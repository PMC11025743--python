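"""On-disk data model: spectra + reference tables, and derived composition.

Canonical dialect is UTF-8 CSV: first column ``sample_id``, spectral columns
headed by the wavelength in nm, property columns headed by the property
name.  XLSX files with the same layout are accepted read-only.  Decimal
commas (Brazilian locale) are handled: dialect "comma" uses ';' separators
with ',' decimals, and "auto" sniffs the separator and decimal marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "ReferenceTable", "read_dataset", "write_dataset", "derive_composition"]


@dataclass(frozen=True)
class SpectraSet:
    """The X matrix: absorbance (log 1/R, a.u.) by sample and wavelength."""

    sample_ids: tuple[str, ...]
    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray  # (n_samples, n_channels)

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if ab.shape != (len(ids), wl.size):
            raise ValueError(
                f"absorbance shape {ab.shape} does not match "
                f"{len(ids)} samples x {wl.size} channels"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance matrix contains non-finite values")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def subset(self, indices) -> "SpectraSet":
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in indices],
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[indices],
        )


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sample laboratory values or fitted kinetic parameters (y vectors).

    Thin wrapper around a DataFrame indexed by sample id; lookup is by
    column name, never by position.  NaN marks a property not measured for
    a sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        vals = df.to_numpy(dtype=float, na_value=np.nan)
        if np.any(np.isinf(vals)):
            raise ValueError("reference values must be finite where present")
        object.__setattr__(self, "data", df.astype(float))

    @classmethod
    def from_arrays(cls, sample_ids, property_names, values) -> "ReferenceTable":
        df = pd.DataFrame(
            np.atleast_2d(np.asarray(values, dtype=float)),
            index=[str(s) for s in sample_ids],
            columns=list(property_names),
        )
        return cls(df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def values_for(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"property {name!r} not in reference table")
        return self.data[name].to_numpy(dtype=float)


def _parse_number(text: str, decimal: str) -> float:
    s = str(text).strip()
    if decimal == ",":
        s = s.replace(".", "").replace(",", ".") if s.count(",") else s
    return float(s)


def _try_wavelength(header: str) -> float | None:
    s = str(header).strip().replace(",", ".")
    try:
        return float(s)
    except ValueError:
        return None


def _sniff_dialect(path: Path) -> tuple[str, str]:
    """Return (sep, decimal) for a CSV by inspecting the first lines."""
    head = path.read_text(encoding="utf-8-sig")[:4096]
    first = head.splitlines()[0] if head else ""
    if first.count(";") > first.count(","):
        return ";", ","
    return ",", "."


def read_dataset(path, dialect: str = "auto") -> tuple[SpectraSet, ReferenceTable]:
    """Read a spectra+reference file (CSV or XLSX).

    Column headers that parse as numbers are wavelengths (nm); the rest are
    property columns.  The wavelength axis is taken from the headers as-is
    -- no step size is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, dtype=object)
    else:
        if dialect == "comma":
            sep, dec = ";", ","
        elif dialect == "point":
            sep, dec = ",", "."
        elif dialect == "auto":
            sep, dec = _sniff_dialect(path)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        raw = pd.read_csv(path, sep=sep, dtype=object, encoding="utf-8-sig")
        if dec == ",":
            raw.columns = [str(c) for c in raw.columns]
    if raw.shape[1] < 2:
        raise ValueError("expected a sample-id column plus data columns")
    id_col = raw.columns[0]
    ids = [str(v).strip() for v in raw[id_col]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated sample ids: {dupes}")

    dec = "," if (dialect == "comma" or (dialect == "auto" and _is_comma_file(raw))) else "."
    wl_cols, prop_cols = [], []
    for c in raw.columns[1:]:
        wl = _try_wavelength(c)
        (wl_cols if wl is not None else prop_cols).append(c)
    if not wl_cols:
        raise ValueError("no wavelength columns found in header")
    wavelengths = np.array([_try_wavelength(c) for c in wl_cols], dtype=float)
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    wl_cols = [wl_cols[i] for i in order]

    spec = np.empty((len(ids), len(wl_cols)))
    for j, col in enumerate(wl_cols):
        for i, cell in enumerate(raw[col]):
            try:
                spec[i, j] = _parse_number(cell, dec)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric spectral value {cell!r} at sample {ids[i]!r}, "
                    f"wavelength column {col!r}"
                ) from None

    props = {}
    for col in prop_cols:
        vals = np.empty(len(ids))
        for i, cell in enumerate(raw[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "nan", "-"):
                vals[i] = np.nan
            else:
                vals[i] = _parse_number(cell, dec)
        props[str(col)] = vals
    ref_df = pd.DataFrame(props, index=ids, dtype=float)
    return (
        SpectraSet(sample_ids=ids, wavelengths=wavelengths, absorbance=spec),
        ReferenceTable(ref_df),
    )


def _is_comma_file(raw: pd.DataFrame) -> bool:
    # heuristic for auto dialect on already-parsed frames: comma decimals
    # survive as strings containing ','
    sample = raw.iloc[: min(len(raw), 5), 1: min(raw.shape[1], 6)]
    return any("," in str(v) for v in sample.to_numpy().ravel())


def write_dataset(spectra: SpectraSet, refs: ReferenceTable | None, path) -> Path:
    """Write the canonical CSV; round-trips through read_dataset to 1e-12."""
    path = Path(path)
    if refs is not None and len(refs.sample_ids) and tuple(refs.sample_ids) != tuple(spectra.sample_ids):
        raise ValueError("spectra and reference table sample ids do not match")
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[format(w, ".10g") for w in spectra.wavelengths],
    )
    if refs is not None and len(refs.property_names):
        for name in refs.property_names:
            df[name] = refs.data[name].to_numpy()
    df.to_csv(path, float_format="%.17g", encoding="utf-8")
    return path


def derive_composition(refs: ReferenceTable) -> ReferenceTable:
    """Add calculated composition columns (all % DM).

    OM = 100 - ash; NFC = OM - CP - apNDF - EE.  Existing columns are left
    untouched; each derived column requires its inputs to be present and is
    only added when currently absent.  A negative computed NFC is retained
    with a warning (it flags inconsistent wet-chemistry inputs, not a bug).
    """
    df = refs.data.copy()
    cols = set(df.columns)
    if "OM" not in cols:
        if "ash" not in cols:
            raise KeyError("deriving OM requires column: ash")
        df["OM"] = 100.0 - df["ash"]
        cols.add("OM")
    if "NFC" not in cols and any(c in cols for c in ("CP", "apNDF", "EE")):
        needed = [c for c in ("OM", "CP", "apNDF", "EE") if c not in cols]
        if needed:
            raise KeyError(f"deriving NFC requires columns: {', '.join(needed)}")
        nfc = df["OM"] - df["CP"] - df["apNDF"] - df["EE"]
        if (nfc.dropna() < 0).any():
            warnings.warn("computed NFC is negative for some samples", stacklevel=2)
        df["NFC"] = nfc
    return ReferenceTable(df)
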