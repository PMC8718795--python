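"""Oligonucleotide physicochemical property encodings: DNP/TNP and DACC/TACC.

A :class:`PropertyTable` assigns each dinucleotide (or trinucleotide) a
value per named property -- conformational and thermodynamic indices such
as twist, roll, slide or stacking energy.  Two encodings are built on it:

- **DNP/TNP** (composition x property): feature(p, o) = relative frequency
  of oligonucleotide *o* in the sequence times the table value of property
  *p* for *o*.  15 dinucleotide properties x 16 dinucleotides = 240 dims;
  12 trinucleotide properties x 64 trinucleotides = 768 dims.
- **DACC/TACC** (auto-cross covariance): the sequence is mapped to one
  numeric signal per property (value of the unit starting at each
  position); for each lag g = 1..lag the auto-covariance of each signal
  and the cross-covariance of each ordered property pair are emitted.
  15 properties, lag 4: 60 + 840 = 900 dims; 12 properties: 48 + 528 = 576.

The bundled tables are synthetic stand-ins (standardized seeded random
values shipped as ``*_synthetic.tsv``); any TSV with an ``oligo`` column
plus one column per property can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd


def _all_oligos(unit_length: int) -> list[str]:
    return ["".join(t) for t in product("ACGT", repeat=unit_length)]


@dataclass
class PropertyTable:
    """Per-oligonucleotide values for a set of named properties.

    ``values`` has shape (n_properties, 4**unit_length), columns ordered
    lexicographically over the oligonucleotides of the unit.
    """

    unit_length: int
    property_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n_oligo = 4**self.unit_length
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.property_names), n_oligo):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.property_names)}, {n_oligo})"
            )

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    @property
    def oligos(self) -> list[str]:
        return _all_oligos(self.unit_length)

    def standardized(self) -> "PropertyTable":
        """Each property centred to mean 0 and scaled to sd 1 across oligos.

        Constant properties are centred only (left at 0 variance).
        """
        v = self.values
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return PropertyTable(self.unit_length, list(self.property_names), (v - mu) / sd)

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "oligo" not in df.columns:
            raise ValueError("property table TSV needs an 'oligo' column")
        unit = len(str(df["oligo"].iloc[0]))
        order = {o: i for i, o in enumerate(_all_oligos(unit))}
        missing = set(order) - set(df["oligo"])
        if missing:
            raise ValueError(f"property table missing oligos, e.g. {sorted(missing)[:3]}")
        df = df.set_index("oligo").loc[_all_oligos(unit)]
        props = [c for c in df.columns]
        return cls(unit, props, df.to_numpy().T)


def load_dinucleotide_table() -> PropertyTable:
    """Bundled 15-property dinucleotide table (synthetic stand-in values)."""
    with resources.as_file(
        resources.files("timgo.data") / "dinucleotide_properties_synthetic.tsv"
    ) as p:
        return PropertyTable.from_tsv(p)


def load_trinucleotide_table() -> PropertyTable:
    """Bundled 12-property trinucleotide table (synthetic stand-in values)."""
    with resources.as_file(
        resources.files("timgo.data") / "trinucleotide_properties_synthetic.tsv"
    ) as p:
        return PropertyTable.from_tsv(p)


def _oligo_indices(seq: str, unit: int) -> np.ndarray:
    """Lexicographic index of the unit starting at each position; -1 for N."""
    su = seq.upper()
    codes = np.full(len(su), -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        codes[np.frombuffer(su.encode(), dtype=np.uint8) == ord(b)] = i
    L = len(su)
    if L < unit:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, unit)
    idx = np.zeros(len(win), dtype=np.int64)
    valid = np.ones(len(win), dtype=bool)
    for j in range(unit):
        idx = idx * 4 + np.where(win[:, j] >= 0, win[:, j], 0)
        valid &= win[:, j] >= 0
    idx[~valid] = -1
    return idx


def property_encode(seq: str, table: PropertyTable) -> np.ndarray:
    """Composition x property vector (DNP for unit 2, TNP for unit 3).

    Output ordered property-major: all oligos of property 1, then
    property 2, etc.  Length = n_properties * 4**unit_length.
    """
    idx = _oligo_indices(seq, table.unit_length)
    idx = idx[idx >= 0]
    n_oligo = 4**table.unit_length
    freq = np.bincount(idx, minlength=n_oligo).astype(float)
    if freq.sum() > 0:
        freq /= freq.sum()
    return (table.values * freq[None, :]).ravel()


@dataclass(frozen=True)
class ACCParams:
    """Auto-cross covariance parameters."""

    table: PropertyTable
    lag: int = 4

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    @property
    def n_features(self) -> int:
        n = self.table.n_properties
        return n * self.lag + n * (n - 1) * self.lag


def acc_encode(seq: str, params: ACCParams) -> np.ndarray:
    """Auto and cross covariances of standardized property signals.

    For property p and lag g: AC(p, g) = mean over i of
    (v_p(i) - mean(v_p)) (v_p(i+g) - mean(v_p)), with v_p(i) the
    standardized table value of the unit at position i; CC analogous for
    ordered pairs p1 != p2.  Output: all AC (property-major, lag-minor),
    then all CC (pair-major in nested property order, lag-minor).
    """
    table = params.table.standardized()
    idx = _oligo_indices(seq, table.unit_length)
    idx = idx[idx >= 0]
    W = len(idx)
    if W <= params.lag:
        raise ValueError(f"sequence yields {W} units; need more than lag={params.lag}")
    signals = table.values[:, idx]  # (n_props, W)
    centered = signals - signals.mean(axis=1, keepdims=True)
    n = table.n_properties
    ac = np.empty((n, params.lag))
    cc = np.empty((n, n, params.lag))
    for g in range(1, params.lag + 1):
        a, b = centered[:, : W - g], centered[:, g:]
        cov = a @ b.T / (W - g)  # (n, n): cov[p1, p2] lagged covariance
        ac[:, g - 1] = np.diag(cov)
        cc[:, :, g - 1] = cov
    out = [ac.ravel()]
    for p1 in range(n):
        for p2 in range(n):
            if p1 != p2:
                out.append(cc[p1, p2, :])
    return np.concatenate(out)
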