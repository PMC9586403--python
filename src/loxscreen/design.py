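"""Biased-randomization ("doped") library design for the 13-bp right RBE.

During solid-phase primer synthesis each of the 13 randomized positions
keeps the wild-type base with probability x/100 (the retention rate) and
is substituted by one of the three alternatives with probability
(100-x)/300 each.  The number of substitutions per molecule, y, is then
Binomial(13, 1 - x/100):

    P(y) = C(13, y) * (x/100)^(13-y) * ((100-x)/100)^y

A retention rate of 84.7% puts the mode of this distribution at y = 2,
the design goal of the screen (double mutants are the most informative
class that can still be covered near-exhaustively).
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb

import numpy as np
import pandas as pd

from .sequences import DNA_ALPHABET, RBE_LENGTH, WT_RBE, lox_site


@dataclasses.dataclass(frozen=True)
class RbeVariant:
    """A right-RBE variant: the 13-mer plus its substitution profile.

    ``n_substitutions`` and ``positions`` (1-based mutated positions) are
    derived from the sequence against the wild type and validated on
    construction.
    """

    sequence: str
    n_substitutions: int = dataclasses.field(init=False)
    positions: frozenset[int] = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        validate_rbe(self.sequence)
        pos = frozenset(
            i + 1 for i, (a, b) in enumerate(zip(self.sequence, WT_RBE)) if a != b
        )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "n_substitutions", len(pos))


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Parameters of the biased randomization.

    retention_pct : per-base probability (in %) of keeping the WT base.
    length        : number of randomized positions (13 for the right RBE).
    """

    retention_pct: float = 84.7
    length: int = RBE_LENGTH

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_pct <= 100.0:
            raise ValueError(
                f"retention_pct must be in [0, 100], got {self.retention_pct}"
            )
        if self.length < 1:
            raise ValueError("length must be positive")

    @property
    def per_alternative_pct(self) -> float:
        """Probability (in %) of each of the three non-WT bases."""
        return (100.0 - self.retention_pct) / 3.0


def validate_rbe(sequence: str) -> str:
    """Check that ``sequence`` is a 13-mer over ACGT; return it."""
    if len(sequence) != RBE_LENGTH:
        raise ValueError(f"RBE must be {RBE_LENGTH} bp, got {len(sequence)!r}")
    if any(b not in DNA_ALPHABET for b in sequence):
        raise ValueError(f"RBE contains non-ACGT characters: {sequence!r}")
    return sequence


def count_substitutions(sequence: str) -> int:
    """Hamming distance of a 13-mer to the wild-type right RBE."""
    validate_rbe(sequence)
    return sum(a != b for a, b in zip(sequence, WT_RBE))


def substitution_count_distribution(spec: DesignSpec) -> np.ndarray:
    """P(y substitutions), y = 0..length, under the doping model.

    Returns an array of length ``spec.length + 1`` summing to 1.
    """
    x = spec.retention_pct / 100.0
    n = spec.length
    y = np.arange(n + 1)
    coef = np.array([comb(n, int(k)) for k in y], dtype=float)
    # 0**0 == 1 handles the x = 0 and x = 1 edges correctly.
    return coef * x ** (n - y) * (1.0 - x) ** y


def enumerate_variant_class(
    k: int, *, materialize: bool = False
) -> int | list[str]:
    """Count (or list) all 13-mers at Hamming distance exactly ``k`` from WT.

    The class size is C(13, k) * 3^k.  Explicit enumeration grows
    exponentially, so the sequence list is only built on request; callers
    should keep ``materialize`` to small ``k`` (the analyses here use
    k <= 2, i.e. at most 702 sequences).
    """
    if not 0 <= k <= RBE_LENGTH:
        raise ValueError(f"k must be in [0, {RBE_LENGTH}], got {k}")
    if not materialize:
        return comb(RBE_LENGTH, k) * 3 ** k
    alternatives = {b: [c for c in DNA_ALPHABET if c != b] for b in DNA_ALPHABET}
    out: list[str] = []
    for positions in itertools.combinations(range(RBE_LENGTH), k):
        choices = [alternatives[WT_RBE[p]] for p in positions]
        for subs in itertools.product(*choices):
            seq = list(WT_RBE)
            for p, b in zip(positions, subs):
                seq[p] = b
            out.append("".join(seq))
    return out


def sample_library(
    spec: DesignSpec, n_variants: int, seed: int | np.random.Generator
) -> list[RbeVariant]:
    """Draw ``n_variants`` RBE molecules from the doping model.

    Each position independently keeps the WT base with probability
    retention_pct/100, else is uniform over the three alternatives.
    Draws are i.i.d.; the same sequence can occur more than once, as in
    a real synthesis pool.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    n, L = n_variants, spec.length
    keep = rng.random((n, L)) < spec.retention_pct / 100.0
    alt_idx = rng.integers(0, 3, size=(n, L))
    wt = np.frombuffer(WT_RBE.encode(), dtype=np.uint8)
    # Alternatives to each base, laid out so row b lists the 3 bases != b.
    alt_table = {
        b: np.frombuffer(
            "".join(c for c in DNA_ALPHABET if c != b).encode(), dtype=np.uint8
        )
        for b in DNA_ALPHABET
    }
    alts = np.stack([alt_table[b] for b in WT_RBE])  # (L, 3)
    drawn = np.where(keep, wt, alts[np.arange(L), alt_idx])
    return [RbeVariant(bytes(row).decode()) for row in drawn]


def coverage_rate(observed: set[str] | list[RbeVariant] | list[str], k: int) -> float:
    """Percent of the k-substitution class present among ``observed``.

    ``observed`` may be sequences or RbeVariant objects; duplicates are
    ignored.  Returns 100 * |distinct observed with k substitutions| /
    (C(13,k) * 3^k).
    """
    if not 0 <= k <= RBE_LENGTH:
        raise ValueError(f"k must be in [0, {RBE_LENGTH}], got {k}")
    seqs = {v.sequence if isinstance(v, RbeVariant) else validate_rbe(v) for v in observed}
    n_hit = sum(count_substitutions(s) == k for s in seqs)
    return 100.0 * n_hit / enumerate_variant_class(k)


def position_composition(
    variants: list[RbeVariant] | list[str],
    weights: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """Per-position base composition of a (weighted) set of RBEs.

    Returns a 13x4 DataFrame (rows = positions 1..13, columns = A,C,G,T)
    of base fractions; each row sums to 1.  Weights default to 1 per
    variant; read counts are the natural choice for sequencing data.
    """
    seqs = [v.sequence if isinstance(v, RbeVariant) else validate_rbe(v) for v in variants]
    if not seqs:
        raise ValueError("no variants given")
    w = np.ones(len(seqs)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(seqs):
        raise ValueError("weights length must match variants")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("all weights are zero")
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), RBE_LENGTH
    )
    counts = np.zeros((RBE_LENGTH, 4))
    for j, base in enumerate(DNA_ALPHABET):
        counts[:, j] = ((mat == ord(base)) * w[:, None]).sum(axis=0)
    frac = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        frac, index=pd.RangeIndex(1, RBE_LENGTH + 1, name="position"),
        columns=list(DNA_ALPHABET),
    )


def library_to_frame(variants: list[RbeVariant]) -> pd.DataFrame:
    """Tabulate a library as variant_sequence / n_substitutions / positions."""
    return pd.DataFrame(
        {
            "variant_sequence": [v.sequence for v in variants],
            "n_substitutions": [v.n_substitutions for v in variants],
            "positions": [
                ",".join(str(p) for p in sorted(v.positions)) for v in variants
            ],
        }
    )


def write_library_tsv(variants: list[RbeVariant], path) -> None:
    library_to_frame(variants).to_csv(path, sep="\t", index=False)


def write_library_fasta(variants: list[RbeVariant], path) -> None:
    """Write full 34-bp mutant loxP sites (left RBE + spacer + variant RBE)."""
    with open(path, "w") as fh:
        for i, v in enumerate(variants):
            fh.write(f">variant_{i}|{v.sequence}|k={v.n_substitutions}\n")
            fh.write(lox_site(v.sequence) + "\n")
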