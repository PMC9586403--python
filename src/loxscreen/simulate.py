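"""Synthetic-data generator for the competitive loxP-vs-lox2272 excision assay.

Each library member is a plasmid cassette carrying two identical mutant
loxP sites and two wild-type lox2272 sites in alternating order:

    5'flank - loxP#1 - markerB - lox2272#1 - stuffer - loxP#2 - markerA - lox2272#2 - 3'flank

Cre excision between the two loxP sites removes markerB (and one
lox2272); excision between the two lox2272 sites removes markerA (and
one loxP).  A read pair therefore encodes the outcome through which
marker tags it contains: both = uncleaved, A only = loxP-excised,
B only = lox2272-excised.  Because both loxP copies carry the same
variant RBE, the variant identity survives every outcome and can be
read out next to the loxP anchor in all three amplicons.

The generator draws per-molecule outcomes from a multinomial over
(non-cleavage, loxP excision, lox2272 excision) and emits one paired-end
read per molecule, with optional i.i.d. substitution errors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import OutcomeCounts
from .design import RbeVariant
from .sequences import (
    DNA_ALPHABET,
    LOX2272_SPACER,
    LOXP_ANCHOR,
    LOX2272_ANCHOR,
    LOXP_SPACER,
    RBE_LENGTH,
    WT_RBE,
    lox_site,
    reverse_complement,
)

MARKER_LENGTH = 24
FLANK_LENGTH = 10
STUFFER_LENGTH = 20
DEFAULT_READ_LENGTH = 150
#: Constant Phred 37 base quality ("F" in Sanger encoding).
QUALITY_CHAR = "F"

OUTCOMES = ("uncleaved", "loxP_cleaved", "lox2272_cleaved")


class MarkerCollisionError(RuntimeError):
    """Raised when random marker tags keep colliding with lox anchors."""


@dataclasses.dataclass(frozen=True)
class Markers:
    """Run-level random sequence elements shared by every construct."""

    marker_a: str
    marker_b: str
    flank5: str
    flank3: str
    stuffer: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one library member.

    p_noncleavage        : probability a molecule escapes excision.
    p_loxP_given_cleaved : probability that, given excision happened, it
                           occurred between the loxP pair (the quantity
                           the pipeline estimates, as a fraction).
    """

    variant: RbeVariant
    p_noncleavage: float
    p_loxP_given_cleaved: float
    n_molecules: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_noncleavage <= 1.0:
            raise ValueError("p_noncleavage must be in [0, 1]")
        if not 0.0 <= self.p_loxP_given_cleaved <= 1.0:
            raise ValueError("p_loxP_given_cleaved must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    @property
    def true_cleavage_rate_pct(self) -> float:
        return 100.0 * self.p_loxP_given_cleaved

    @property
    def true_non_cleavage_rate_pct(self) -> float:
        return 100.0 * self.p_noncleavage


@dataclasses.dataclass(frozen=True)
class ConstructTemplate:
    """A concrete cassette sequence with 0-based half-open coordinates."""

    variant: RbeVariant
    sequence: str
    elements: dict  # name -> (start, end)
    markers: Markers

    def element_seq(self, name: str) -> str:
        s, e = self.elements[name]
        return self.sequence[s:e]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))

_FORBIDDEN = (LOXP_ANCHOR, LOX2272_ANCHOR,
              reverse_complement(LOXP_ANCHOR), reverse_complement(LOX2272_ANCHOR),
              LOXP_ANCHOR[:13], reverse_complement(LOXP_ANCHOR[:13]))


def draw_markers(seed: int | np.random.Generator, max_tries: int = 100) -> Markers:
    """Draw the run-level marker tags, flanks and stuffer.

    Tags are redrawn if they contain a lox anchor or left-RBE substring
    (so marker matches can never be spurious lox hits), or if the two
    markers overlap as strings.
    """
    rng = np.random.default_rng(seed)

    def draw(length: int) -> str:
        for _ in range(max_tries):
            s = _random_dna(rng, length)
            if not any(f in s for f in _FORBIDDEN):
                return s
        raise MarkerCollisionError(
            f"could not draw a {length}-mer clear of lox anchors in {max_tries} tries"
        )

    marker_a = draw(MARKER_LENGTH)
    marker_b = draw(MARKER_LENGTH)
    for _ in range(max_tries):
        if marker_a not in marker_b and marker_b not in marker_a:
            break
        marker_b = draw(MARKER_LENGTH)
    else:  # pragma: no cover - probability ~0
        raise MarkerCollisionError("marker tags kept overlapping")
    return Markers(
        marker_a=marker_a,
        marker_b=marker_b,
        flank5=draw(FLANK_LENGTH),
        flank3=draw(FLANK_LENGTH),
        stuffer=draw(STUFFER_LENGTH),
    )


def build_construct(
    variant: RbeVariant, markers: Markers | int
) -> ConstructTemplate:
    """Assemble the uncleaved cassette for one variant.

    ``markers`` is normally a run-level :class:`Markers` object so every
    construct in a run shares the same tags; passing an integer draws a
    fresh set from that seed (deterministic).
    """
    if not isinstance(markers, Markers):
        markers = draw_markers(markers)
    loxp = lox_site(variant.sequence, LOXP_SPACER)
    lox2272 = lox_site(WT_RBE, LOX2272_SPACER)
    parts = [
        ("flank5", markers.flank5),
        ("loxP_1", loxp),
        ("markerB", markers.marker_b),
        ("lox2272_1", lox2272),
        ("stuffer", markers.stuffer),
        ("loxP_2", loxp),
        ("markerA", markers.marker_a),
        ("lox2272_2", lox2272),
        ("flank3", markers.flank3),
    ]
    elements, pos, chunks = {}, 0, []
    for name, seq in parts:
        elements[name] = (pos, pos + len(seq))
        chunks.append(seq)
        pos += len(seq)
    return ConstructTemplate(
        variant=variant, sequence="".join(chunks), elements=elements, markers=markers
    )


def _spacer_midpoint(construct: ConstructTemplate, element: str) -> int:
    start, _ = construct.elements[element]
    # left RBE (13) + half of the 8-bp spacer
    return start + RBE_LENGTH + 4


def excision_products(construct: ConstructTemplate) -> dict[str, str]:
    """The three possible amplicons for one construct.

    Excision removes the segment between the spacer midpoints of the two
    compatible sites, leaving a single hybrid site; because both loxP
    copies carry the identical variant RBE, the hybrid loxP still reads
    anchor + variant RBE.
    """
    seq = construct.sequence
    lp = seq[: _spacer_midpoint(construct, "loxP_1")] + seq[
        _spacer_midpoint(construct, "loxP_2"):
    ]
    l22 = seq[: _spacer_midpoint(construct, "lox2272_1")] + seq[
        _spacer_midpoint(construct, "lox2272_2"):
    ]
    return {"uncleaved": seq, "loxP_cleaved": lp, "lox2272_cleaved": l22}


def simulate_outcomes(
    truth: TruthRecord, seed: int | np.random.Generator
) -> OutcomeCounts:
    """Draw molecule-level outcome counts from the multinomial model."""
    rng = np.random.default_rng(seed)
    p_nc = truth.p_noncleavage
    p_lp = (1.0 - p_nc) * truth.p_loxP_given_cleaved
    p_l22 = (1.0 - p_nc) * (1.0 - truth.p_loxP_given_cleaved)
    n_unc, n_lp, n_l22 = rng.multinomial(truth.n_molecules, [p_nc, p_lp, p_l22])
    return OutcomeCounts(
        n_uncleaved=int(n_unc),
        n_loxP_cleaved=int(n_lp),
        n_lox2272_cleaved=int(n_l22),
    )


def _read_pair(amplicon: str, read_len: int) -> tuple[str, str]:
    r1 = amplicon[:read_len]
    r2 = reverse_complement(amplicon)[:read_len]
    return r1, r2


def _inject_errors(read: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return read
    n_err = rng.binomial(len(read), error_rate)
    if n_err == 0:
        return read
    out = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        out[pos] = rng.choice([b for b in DNA_ALPHABET if b != out[pos]])
    return "".join(out)


def simulate_read_pairs(
    library: list[TruthRecord],
    markers: Markers,
    *,
    read_len: int = DEFAULT_READ_LENGTH,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Yield (read_id, mate1, mate2) for every molecule in the library.

    The read id embeds the source variant and true outcome
    (``mol<i>|<variant>|<outcome>``), the convention of read simulators,
    so downstream calls can be scored against truth without a side table.
    """
    if not library:
        raise ValueError("library is empty")
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    mol = 0
    for truth in library:
        construct = build_construct(truth.variant, markers)
        products = excision_products(construct)
        counts = simulate_outcomes(truth, rng)
        for outcome, n in zip(
            OUTCOMES,
            (counts.n_uncleaved, counts.n_loxP_cleaved, counts.n_lox2272_cleaved),
        ):
            r1t, r2t = _read_pair(products[outcome], read_len)
            for _ in range(n):
                r1 = _inject_errors(r1t, error_rate, rng)
                r2 = _inject_errors(r2t, error_rate, rng)
                yield f"mol{mol}|{truth.variant.sequence}|{outcome}", r1, r2
                mol += 1


def truth_table(library: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_sequence": [t.variant.sequence for t in library],
            "n_substitutions": [t.variant.n_substitutions for t in library],
            "p_noncleavage": [t.p_noncleavage for t in library],
            "p_loxP_given_cleaved": [t.p_loxP_given_cleaved for t in library],
            "true_cleavage_rate_pct": [t.true_cleavage_rate_pct for t in library],
            "n_molecules": [t.n_molecules for t in library],
        }
    )


def generate_fastq(
    library: list[TruthRecord],
    out_dir: str | Path,
    *,
    read_len: int = DEFAULT_READ_LENGTH,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write reads_R1/R2.fastq, truth.tsv and markers.yaml for a library.

    Markers are drawn from ``seed`` and recorded in markers.yaml so the
    classifier can be configured from the same file.  Output is
    byte-identical for a fixed (library, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    markers = draw_markers(seed)
    paths = {
        "r1": out_dir / "reads_R1.fastq",
        "r2": out_dir / "reads_R2.fastq",
        "truth": out_dir / "truth.tsv",
        "markers": out_dir / "markers.yaml",
    }
    try:
        with open(paths["r1"], "w") as f1, open(paths["r2"], "w") as f2:
            for rid, r1, r2 in simulate_read_pairs(
                library, markers, read_len=read_len, error_rate=error_rate, seed=seed
            ):
                f1.write(f"@{rid}/1\n{r1}\n+\n{QUALITY_CHAR * len(r1)}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{QUALITY_CHAR * len(r2)}\n")
    except OSError as exc:  # surface I/O failures with file context
        raise OSError(f"failed writing FASTQ under {out_dir}: {exc}") from exc
    truth_table(library).to_csv(paths["truth"], sep="\t", index=False)
    config = {
        "marker_a": markers.marker_a,
        "marker_b": markers.marker_b,
        "loxP_anchor": LOXP_ANCHOR,
        "lox2272_anchor": LOX2272_ANCHOR,
        "read_len": read_len,
        "error_rate": error_rate,
        "seed": seed,
        "flank5": markers.flank5,
        "flank3": markers.flank3,
        "stuffer": markers.stuffer,
    }
    with open(paths["markers"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths


def default_truth_model(
    variants: list[RbeVariant],
    *,
    n_molecules: int = 2000,
    p_noncleavage: float = 0.035,
    seed: int | np.random.Generator = 0,
) -> list[TruthRecord]:
    """Assign plausible true rates to a library of variants.

    The wild type competes symmetrically with the lox2272 pair, so its
    loxP-excision share is 0.5; affinity loss with each substitution is
    modelled as a geometric decay exp(-0.18 k) with per-variant
    lognormal jitter (sigma = 0.15), clipped to [0.005, 0.60].  This
    spans roughly 0.5%-60%, the dynamic range the assay resolves.
    """
    rng = np.random.default_rng(seed)
    records = []
    for v in variants:
        base = 0.5 * np.exp(-0.18 * v.n_substitutions)
        p = float(np.clip(base * rng.lognormal(0.0, 0.15), 0.005, 0.60))
        records.append(
            TruthRecord(
                variant=v,
                p_noncleavage=p_noncleavage,
                p_loxP_given_cleaved=p,
                n_molecules=n_molecules,
            )
        )
    return records
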