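"""Synthetic hot/cold sequence datasets with planted compositional signal.

Recombination hotspots are known to differ from coldspots in GC content
and dinucleotide bias, and the regions of interest span roughly 1-2.5 kb.
The generator emulates exactly that structure: the cold class draws
i.i.d. bases from a background composition, while the hot class draws
from a first-order Markov chain whose transition matrix up-weights the
constituent dinucleotides of the planted k-mers by configurable
enrichment factors (and applies an optional GC shift), then renormalizes.
A first-order dinucleotide bias is used rather than motif insertion
because every feature family the encoder computes — k-mer tiers and
PseDNC couplings — responds to dinucleotide statistics, so the planted
signal is detectable by the method under test without being trivially
separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .sequences import ALPHABET, DnaSequence, write_fasta


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the benchmark class ratio (490 hotspots / 591
    coldspots), region lengths of 1-2.5 kb, a uniform background, and a
    planted CG dinucleotide enrichment of 3.0 in the hot class.
    """

    n_hot: int = 490
    n_cold: int = 591
    length_range: Tuple[int, int] = (1000, 2500)
    background: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_kmers: Tuple[Tuple[str, float], ...] = (("CG", 3.0),)
    gc_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hot < 1 or self.n_cold < 1:
            raise ValueError("both class counts must be positive")
        lo, hi = self.length_range
        if lo < 12 or hi < lo:
            raise ValueError("length range must satisfy 12 <= min <= max")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        for mer, factor in self.planted_kmers:
            if len(mer) < 2 or any(b not in ALPHABET for b in mer.upper()):
                raise ValueError(f"planted k-mer {mer!r} must be >= 2 nt over ACGT")
            if factor <= 0:
                raise ValueError(f"enrichment factor for {mer!r} must be positive")
        gc = bg[1] + bg[2]
        if not (0 <= gc + self.gc_shift <= 1) or (gc == 0 and self.gc_shift != 0):
            raise ValueError("gc_shift drives GC content outside [0, 1]")


def hot_transition_matrix(config: SyntheticConfig) -> np.ndarray:
    """Row-stochastic transition matrix of the hot-class Markov chain."""
    bg = np.asarray(config.background, dtype=float)
    T = np.tile(bg, (4, 1))
    for mer, factor in config.planted_kmers:
        mer = mer.upper()
        for x, y in zip(mer, mer[1:]):
            T[ALPHABET.index(x), ALPHABET.index(y)] *= factor
    if config.gc_shift != 0.0:
        gc = bg[1] + bg[2]
        scale = np.array(
            [
                (1 - gc - config.gc_shift) / (1 - gc),
                (gc + config.gc_shift) / gc,
                (gc + config.gc_shift) / gc,
                (1 - gc - config.gc_shift) / (1 - gc),
            ]
        )
        T *= scale
    rowsums = T.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError("enrichment drives a transition row to all-zero")
    return T / rowsums[:, None]


def _markov_sequence(rng: np.random.Generator, length: int, T: np.ndarray) -> str:
    bg = T.mean(axis=0)
    bases = np.empty(length, dtype=np.intp)
    bases[0] = rng.choice(4, p=bg / bg.sum())
    # inverse-CDF sampling against per-row cumulative probabilities
    cum = np.cumsum(T, axis=1)
    u = rng.random(length - 1)
    for i in range(1, length):
        bases[i] = np.searchsorted(cum[bases[i - 1]], u[i - 1])
    return "".join(ALPHABET[b] for b in bases)


def generate_dataset(
    config: SyntheticConfig,
) -> Tuple[List[DnaSequence], np.ndarray]:
    """Generate labeled sequences: +1 hot (Markov-biased), -1 cold (i.i.d.).

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    bg = np.asarray(config.background, dtype=float)
    T = hot_transition_matrix(config)

    seqs: List[DnaSequence] = []
    labels: List[int] = []
    for i in range(config.n_hot):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(DnaSequence(id=f"hot_{i}", residues=_markov_sequence(rng, length, T)))
        labels.append(1)
    for i in range(config.n_cold):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(ALPHABET[b] for b in rng.choice(4, size=length, p=bg))
        seqs.append(DnaSequence(id=f"cold_{i}", residues=residues))
        labels.append(-1)
    return seqs, np.array(labels)


def write_dataset(
    outdir: Union[str, Path],
    seqs: Sequence[DnaSequence],
    labels: np.ndarray,
    config: SyntheticConfig,
) -> None:
    """Emit hot.fasta / cold.fasta, a labels TSV and a JSON config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hot = [s for s, y in zip(seqs, labels) if y == 1]
    cold = [s for s, y in zip(seqs, labels) if y == -1]
    write_fasta(outdir / "hot.fasta", hot)
    write_fasta(outdir / "cold.fasta", cold)
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("id\tlabel\n")
        for s, y in zip(seqs, labels):
            fh.write(f"{s.id}\t{int(y)}\n")
    sidecar = {
        "n_hot": config.n_hot,
        "n_cold": config.n_cold,
        "length_range": list(config.length_range),
        "background": list(config.background),
        "planted_kmers": [[m, f] for m, f in config.planted_kmers],
        "gc_shift": config.gc_shift,
        "seed": config.seed,
    }
    (outdir / "config.json").write_text(json.dumps(sidecar, indent=2))


def planted_feature_names(config: SyntheticConfig, k_max: int) -> List[str]:
    """Feature names that directly measure the planted signal.

    All k-mer features (tiers 1..k_max) containing a planted k-mer as a
    substring, plus the PseDNC dinucleotide components matching planted
    dinucleotides.
    """
    mers = [m.upper() for m, _ in config.planted_kmers]
    names: List[str] = []
    for k in range(2, k_max + 1):
        kmers = [""]
        for _ in range(k):
            kmers = [s + b for s in kmers for b in ALPHABET]
        names.extend("kmer:" + s for s in kmers if any(m in s for m in mers))
    names.extend("pse:" + m for m in mers if len(m) == 2)
    return names
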