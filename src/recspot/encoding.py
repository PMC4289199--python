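"""Pseudo nucleic acid composition (PseNAC) feature encoding.

A DNA sequence is represented by the concatenation of

* nucleic acid composition (NAC) and its higher tiers: normalized
  overlapping k-mer frequencies for k = 1..k_max (4^k features per tier),
* pseudo dinucleotide composition (PseDNC): the 16 dinucleotide
  frequencies augmented with omega global sequence-order correlation
  factors g_1..g_omega built from a physicochemical dissimilarity Delta
  between dinucleotides at increasing lags.

Delta between two dinucleotides is the mean squared difference of their
J = 6 normalized structural properties (twist, tilt, roll, shift, slide,
rise); g_j averages Delta over all dinucleotide pairs separated by lag j.
The PseDNC block is normalized so that it sums to one:

    d_m     = f_m / (sum_f + w * sum_g)        m = 1..16
    d_{16+j} = w * g_j / (sum_f + w * sum_g)    j = 1..omega

where w is a weight factor (default 0.05) balancing local composition
against global order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .sequences import ALPHABET, DnaSequence

PROPERTY_NAMES = ("twist", "tilt", "roll", "shift", "slide", "rise")
DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

DEFAULT_K_MAX = 5
DEFAULT_OMEGA = 10
DEFAULT_WEIGHT = 0.05


class PhysicoChemTable:
    """16 dinucleotides x 6 normalized structural properties.

    The packaged default table ships with the library; users may supply an
    alternative table of the same shape (TSV with a ``dinucleotide`` column
    followed by the six property columns).
    """

    def __init__(self, values: pd.DataFrame):
        missing = set(DINUCLEOTIDES) - set(values.index)
        if missing:
            raise ValueError(f"table is missing dinucleotides: {sorted(missing)}")
        if list(values.columns) != list(PROPERTY_NAMES):
            raise ValueError(
                f"table columns must be {PROPERTY_NAMES}, got {list(values.columns)}"
            )
        self.values = values.loc[list(DINUCLEOTIDES)].astype(float)
        # Delta over all ordered pairs, precomputed: mean squared property
        # difference (J = 6).
        v = self.values.to_numpy()
        diff = v[:, None, :] - v[None, :, :]
        self._delta = (diff**2).mean(axis=2)

    @classmethod
    def default(cls) -> "PhysicoChemTable":
        with resources.files("recspot.data").joinpath(
            "dinucleotide_properties.tsv"
        ).open() as fh:
            df = pd.read_csv(fh, sep="\t", index_col="dinucleotide")
        return cls(df)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PhysicoChemTable":
        return cls(pd.read_csv(path, sep="\t", index_col="dinucleotide"))

    @property
    def delta_matrix(self) -> np.ndarray:
        """(16, 16) matrix of Delta values indexed by dinucleotide code."""
        return self._delta

    def delta(self, d1: str, d2: str) -> float:
        for d in (d1, d2):
            if d not in _DINUC_INDEX:
                raise KeyError(f"unknown dinucleotide {d!r}")
        return float(self._delta[_DINUC_INDEX[d1], _DINUC_INDEX[d2]])


@dataclass(frozen=True)
class PseDncParams:
    """PseDNC hyperparameters: highest coupling rank omega and weight w."""

    omega: int = DEFAULT_OMEGA
    weight: float = DEFAULT_WEIGHT

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValueError(f"omega must be >= 1, got {self.omega}")
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered feature blocks of the merged PseNAC vector.

    Block order is fixed: k-mer tier 1..k_max (each 4^k names in
    lexicographic A<C<G<T order), then the PseDNC block (16 dinucleotide
    components followed by omega lag components).
    """

    k_max: int
    omega: int
    blocks: Tuple[Tuple[str, Tuple[str, ...]], ...] = field(init=False)

    def __post_init__(self) -> None:
        blocks = []
        for k in range(1, self.k_max + 1):
            names = tuple("kmer:" + m for m in _kmers(k))
            blocks.append((f"kmer{k}", names))
        pse = tuple("pse:" + d for d in DINUCLEOTIDES) + tuple(
            f"pse:{j}" for j in range(1, self.omega + 1)
        )
        blocks.append(("psednc", pse))
        object.__setattr__(self, "blocks", tuple(blocks))

    @property
    def names(self) -> List[str]:
        return [n for _, block in self.blocks for n in block]

    @property
    def dim(self) -> int:
        return sum(len(block) for _, block in self.blocks)

    def block_of(self, name: str) -> str:
        """Coarse family of a feature name: ``kmer`` or ``psednc``."""
        return "kmer" if name.startswith("kmer:") else "psednc"

    def block_slices(self) -> Dict[str, slice]:
        out, start = {}, 0
        for bname, block in self.blocks:
            out[bname] = slice(start, start + len(block))
            start += len(block)
        return out


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout: FeatureLayout


def _kmers(k: int) -> List[str]:
    mers = [""]
    for _ in range(k):
        mers = [m + b for m in mers for b in ALPHABET]
    return mers


def kmer_frequencies(seq: DnaSequence, k: int) -> np.ndarray:
    """Normalized overlapping k-mer frequencies, lexicographic A<C<G<T order.

    Entry for k-mer m is count(m, overlapping windows) / (L - k + 1).
    """
    L = len(seq)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L} (record {seq.id!r})")
    idx = seq.indices()
    codes = idx[: L - k + 1].copy()
    for t in range(1, k):
        codes = codes * 4 + idx[t : L - k + 1 + t]
    counts = np.bincount(codes, minlength=4**k)
    return counts / (L - k + 1)


def delta(d1: str, d2: str, table: PhysicoChemTable) -> float:
    """Coupling-mode dissimilarity: mean squared difference over J=6 properties."""
    return table.delta(d1, d2)


def _dinuc_codes(seq: DnaSequence) -> np.ndarray:
    idx = seq.indices()
    return idx[:-1] * 4 + idx[1:]


def correlation_factor(seq: DnaSequence, j: int, table: PhysicoChemTable) -> float:
    """Global sequence-order factor g_j: mean Delta between dinucleotides at lag j."""
    L = len(seq)
    if j < 1 or j > L - 2:
        raise ValueError(
            f"lag j={j} out of range 1..{L - 2} for sequence {seq.id!r} (L={L})"
        )
    di = _dinuc_codes(seq)
    return float(table.delta_matrix[di[: L - 1 - j], di[j:]].mean())


def correlation_factors(
    seq: DnaSequence, omega: int, table: PhysicoChemTable
) -> np.ndarray:
    """g_1..g_omega as a vector."""
    return np.array([correlation_factor(seq, j, table) for j in range(1, omega + 1)])


def psednc_vector(
    seq: DnaSequence, params: PseDncParams, table: PhysicoChemTable
) -> np.ndarray:
    """Pseudo dinucleotide composition: 16 + omega entries summing to one."""
    L = len(seq)
    if L < params.omega + 2:
        raise ValueError(
            f"sequence {seq.id!r} has length {L} < omega + 2 = {params.omega + 2}"
        )
    f = kmer_frequencies(seq, 2)
    g = correlation_factors(seq, params.omega, table)
    denom = f.sum() + params.weight * g.sum()
    return np.concatenate([f, params.weight * g]) / denom


def encode_psenac(
    seq: DnaSequence,
    k_max: int = DEFAULT_K_MAX,
    params: PseDncParams = PseDncParams(),
    table: PhysicoChemTable | None = None,
) -> FeatureVector:
    """Merged PseNAC vector: k-mer tiers 1..k_max then the PseDNC block."""
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if table is None:
        table = PhysicoChemTable.default()
    tiers = [kmer_frequencies(seq, k) for k in range(1, k_max + 1)]
    pse = psednc_vector(seq, params, table)
    layout = FeatureLayout(k_max=k_max, omega=params.omega)
    return FeatureVector(values=np.concatenate(tiers + [pse]), layout=layout)


def encode_dataset(
    seqs: Sequence[DnaSequence],
    k_max: int = DEFAULT_K_MAX,
    params: PseDncParams = PseDncParams(),
    table: PhysicoChemTable | None = None,
) -> Tuple[np.ndarray, FeatureLayout]:
    """Encode a dataset into a (n, D) matrix sharing one layout.

    The omega cap is validated against the minimum sequence length of this
    dataset (every g_j must have at least one term).
    """
    if not seqs:
        raise ValueError("cannot encode an empty dataset")
    l_min = min(len(s) for s in seqs)
    if params.omega > l_min - 2:
        short = min(seqs, key=len)
        raise ValueError(
            f"omega={params.omega} exceeds L_min - 2 = {l_min - 2} "
            f"(shortest sequence: {short.id!r}, length {l_min})"
        )
    if table is None:
        table = PhysicoChemTable.default()
    layout = FeatureLayout(k_max=k_max, omega=params.omega)
    X = np.empty((len(seqs), layout.dim))
    for i, s in enumerate(seqs):
        X[i] = encode_psenac(s, k_max, params, table).values
    return X, layout


def write_matrix_tsv(
    path: Union[str, Path],
    X: np.ndarray,
    layout: FeatureLayout,
    ids: Sequence[str],
    labels: Sequence[int] | None = None,
) -> None:
    """Feature matrix as TSV: header = feature names, first column = id."""
    df = pd.DataFrame(X, columns=layout.names)
    df.insert(0, "id", list(ids))
    if labels is not None:
        df.insert(1, "label", list(labels))
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: Union[str, Path]):
    """Read a feature matrix TSV back as (X, feature names, ids, labels or None)."""
    df = pd.read_csv(path, sep="\t")
    ids = df.pop("id").tolist()
    labels = df.pop("label").to_numpy(int) if "label" in df.columns else None
    return df.to_numpy(float), list(df.columns), ids, labels
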