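"""Classify paired-end amplicon reads into Cre recombination outcomes.

The analysis is pure exact substring matching, mirroring the script-level
treatment such amplicon screens use:

1. *Variant extraction* — find the 21-bp loxP anchor (left RBE + loxP
   spacer) in either mate or its reverse complement; the 13 bases that
   follow are the variant right RBE.  All complete anchor hits within a
   pair must agree, otherwise the pair is dropped as an extraction
   failure (a disagreement usually means a sequencing error).
2. *Outcome call* — two diagnostic marker tags encode the outcome:
   marker A survives only loxP excision, marker B only lox2272 excision.
   Both present = uncleaved; A only = cleaved between loxP; B only =
   cleaved between lox2272; neither = unclassified.
3. *Rates* — per variant,

       cleavage rate (%)     = 100 * n_loxP / (n_loxP + n_lox2272)
       non-cleavage rate (%) = 100 * n_unc  / (n_unc + n_loxP + n_lox2272)

   Unclassified pairs never enter a denominator.  Variants are reported
   with a read-count threshold flag (strictly more than ``cutoff``
   classified-or-unclassified pairs, default 500).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import count_substitutions
from .sequences import DNA_ALPHABET, LOXP_ANCHOR, RBE_LENGTH, reverse_complement

DEFAULT_CUTOFF = 500

UNCLEAVED = "uncleaved"
LOXP_CLEAVED = "loxP_cleaved"
LOX2272_CLEAVED = "lox2272_cleaved"
UNCLASSIFIED = "unclassified"


class UndefinedRateError(ZeroDivisionError):
    """A rate whose denominator is empty (no informative reads)."""


@dataclasses.dataclass
class OutcomeCounts:
    """Per-variant tally of read-pair outcomes."""

    n_uncleaved: int = 0
    n_loxP_cleaved: int = 0
    n_lox2272_cleaved: int = 0
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.n_uncleaved
            + self.n_loxP_cleaved
            + self.n_lox2272_cleaved
            + self.n_unclassified
        )

    @property
    def n_classified(self) -> int:
        return self.total - self.n_unclassified

    def add(self, outcome: str) -> None:
        if outcome == UNCLEAVED:
            self.n_uncleaved += 1
        elif outcome == LOXP_CLEAVED:
            self.n_loxP_cleaved += 1
        elif outcome == LOX2272_CLEAVED:
            self.n_lox2272_cleaved += 1
        elif outcome == UNCLASSIFIED:
            self.n_unclassified += 1
        else:
            raise ValueError(f"unknown outcome {outcome!r}")


def _extract_from_text(text: str, anchor: str) -> tuple[set[str], bool]:
    """All complete 13-mers following anchor hits in one string.

    Returns (extracted set, saw_truncated): a hit too close to the 3'
    end to yield a full RBE is flagged rather than extracted.
    """
    found: set[str] = set()
    truncated = False
    start = 0
    while (pos := text.find(anchor, start)) != -1:
        rbe = text[pos + len(anchor): pos + len(anchor) + RBE_LENGTH]
        if len(rbe) == RBE_LENGTH:
            found.add(rbe)
        else:
            truncated = True
        start = pos + 1
    return found, truncated


def extract_variant(
    mate1: str, mate2: str, anchor: str = LOXP_ANCHOR
) -> str | None:
    """Extract the variant RBE from a read pair, or None on failure.

    Both mates and their reverse complements are scanned for exact
    anchor matches.  Failure (None) means: no complete hit anywhere,
    discordant RBEs between hits, or a non-ACGT character in the
    extracted window.
    """
    rbes: set[str] = set()
    for text in (mate1, mate2, reverse_complement(mate1), reverse_complement(mate2)):
        found, _ = _extract_from_text(text, anchor)
        rbes |= found
    if len(rbes) != 1:
        return None
    rbe = next(iter(rbes))
    if any(b not in DNA_ALPHABET for b in rbe):
        return None
    return rbe


def classify_pair(
    mate1: str, mate2: str, marker_a: str, marker_b: str
) -> str:
    """Call the recombination outcome of one read pair from its markers."""
    if marker_a == marker_b:
        raise ValueError("marker_a and marker_b must differ")
    text = mate1 + "#" + mate2
    rc = reverse_complement(mate2) + "#" + reverse_complement(mate1)
    has_a = marker_a in text or marker_a in rc
    has_b = marker_b in text or marker_b in rc
    if has_a and has_b:
        return UNCLEAVED
    if has_a:
        return LOXP_CLEAVED
    if has_b:
        return LOX2272_CLEAVED
    return UNCLASSIFIED


@dataclasses.dataclass
class TallyResult:
    counts: dict[str, OutcomeCounts]
    n_pairs: int
    n_extraction_failures: int


def tally(
    pairs: Iterable[tuple[str, str]],
    marker_a: str,
    marker_b: str,
    anchor: str = LOXP_ANCHOR,
) -> TallyResult:
    """Stream read pairs into per-variant outcome counts.

    Memory is bounded by the number of distinct variants.  Pairs whose
    variant cannot be extracted go to a global failure counter; every
    other pair lands in exactly one (variant, outcome) cell.
    """
    counts: dict[str, OutcomeCounts] = {}
    n_pairs = n_fail = 0
    for mate1, mate2 in pairs:
        n_pairs += 1
        variant = extract_variant(mate1, mate2, anchor)
        if variant is None:
            n_fail += 1
            continue
        outcome = classify_pair(mate1, mate2, marker_a, marker_b)
        counts.setdefault(variant, OutcomeCounts()).add(outcome)
    return TallyResult(counts=counts, n_pairs=n_pairs, n_extraction_failures=n_fail)


def cleavage_rate(counts: OutcomeCounts) -> float:
    """Percent of excision events that occurred between the loxP pair."""
    denom = counts.n_loxP_cleaved + counts.n_lox2272_cleaved
    if denom == 0:
        raise UndefinedRateError("no cleaved reads: loxP cleavage rate undefined")
    return 100.0 * counts.n_loxP_cleaved / denom


def non_cleavage_rate(counts: OutcomeCounts) -> float:
    """Percent of classified molecules that escaped excision."""
    denom = counts.n_classified
    if denom == 0:
        raise UndefinedRateError("no classified reads: non-cleavage rate undefined")
    return 100.0 * counts.n_uncleaved / denom


def read_pair_stream(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str]]:
    """Iterate synchronized mate sequences from two FASTQ files."""
    i = -1
    try:
        with open(r1_path) as f1, open(r2_path) as f2:
            it1 = FastqGeneralIterator(f1)
            it2 = FastqGeneralIterator(f2)
            for i, (rec1, rec2) in enumerate(zip(it1, it2, strict=True)):
                yield rec1[1], rec2[1]
    except ValueError as exc:
        raise ValueError(
            f"unreadable or unpaired FASTQ record near index {i + 1} "
            f"({r1_path} / {r2_path}): {exc}"
        ) from exc


def load_markers(path: str | Path) -> dict:
    """Read the markers.yaml config written by the simulator."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def estimates_from_tally(
    result: TallyResult, cutoff: int = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Per-variant cleavage estimates, sorted by ascending cleavage rate.

    Variants with no cleaved reads get NaN rates but are still listed.
    ``passes_cutoff`` is strict: the pair count must exceed ``cutoff``.
    """
    rows = []
    for variant, c in result.counts.items():
        try:
            cr = cleavage_rate(c)
        except UndefinedRateError:
            cr = float("nan")
        try:
            ncr = non_cleavage_rate(c)
        except UndefinedRateError:
            ncr = float("nan")
        rows.append(
            {
                "variant_sequence": variant,
                "n_substitutions": count_substitutions(variant),
                "n_uncleaved": c.n_uncleaved,
                "n_loxP": c.n_loxP_cleaved,
                "n_lox2272": c.n_lox2272_cleaved,
                "n_unclassified": c.n_unclassified,
                "n_reads": c.total,
                "cleavage_rate_pct": cr,
                "non_cleavage_rate_pct": ncr,
                "passes_cutoff": c.total > cutoff,
            }
        )
    if not rows:
        raise ValueError("no classifiable reads: empty tally")
    return (
        pd.DataFrame(rows)
        .sort_values("cleavage_rate_pct", kind="mergesort", na_position="last")
        .reset_index(drop=True)
    )


def estimate_library(
    r1_path: str | Path,
    r2_path: str | Path,
    markers: dict | str | Path,
    cutoff: int = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """End-to-end: paired FASTQ + marker config -> per-variant estimates."""
    if not isinstance(markers, dict):
        markers = load_markers(markers)
    result = tally(
        read_pair_stream(r1_path, r2_path),
        marker_a=markers["marker_a"],
        marker_b=markers["marker_b"],
        anchor=markers.get("loxP_anchor", LOXP_ANCHOR),
    )
    return estimates_from_tally(result, cutoff=cutoff)


def write_estimates_tsv(estimates: pd.DataFrame, path: str | Path) -> None:
    """Write estimates with rates rounded to 1 decimal (full precision kept in memory)."""
    out = estimates.copy()
    for col in ("cleavage_rate_pct", "non_cleavage_rate_pct"):
        out[col] = out[col].round(1)
    out.to_csv(path, sep="\t", index=False)
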