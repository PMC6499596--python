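"""Capture-experiment statistics and the in-silico PCR species check.

Covers the quantities used to characterise magnetic single-cell sorting:
capture efficiency (captured positives / laser-targeted cells) and its
linear fit across experiments, sample purity / contamination, fold
enrichment of a rare population, and an exact-match in-silico PCR that
reports amplicon lengths for a primer pair on a template sequence (used to
verify species-specific mitochondrial cytochrome-b products).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

_DNA = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CaptureResult:
    """Counts from one sorting experiment."""

    experiment_id: str
    n_targeted: float
    n_captured_positive: float
    n_captured_negative: float = 0.0
    substrate: str = "other"  # glass | aclar | other
    n_rounds: int = 1

    def __post_init__(self) -> None:
        if min(self.n_targeted, self.n_captured_positive,
               self.n_captured_negative) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_captured_positive > self.n_targeted:
            raise ValueError("cannot capture more positives than targeted")


@dataclass
class PrimerPair:
    """A named PCR primer pair, both given 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for seq in (self.forward, self.reverse):
            if not _DNA.match(seq):
                raise ValueError("primers must be A/C/G/T only")
            if len(seq) < 10:
                raise ValueError("primers must be at least 10 nt")


# printed mitochondrial cytochrome-b primer pairs (dog: 247 nt product;
# mouse: 196 nt product on the authentic genes)
CYTB_DOG = PrimerPair("Cytb1_dog", "CATAGCCACAGCATTCATGG",
                      "GGATCCGGTTTCGTGTAGAA")
CYTB_MOUSE = PrimerPair("Cytb2_mouse", "CCTCAAAGCAACGAAGCCTA",
                        "TCTTCGATAATTCCTGAGATTGG")


def efficiency(result: CaptureResult) -> float:
    """Capture efficiency: captured positive cells / targeted cells."""
    if result.n_targeted <= 0:
        raise ValueError("efficiency undefined for zero targeted cells")
    return result.n_captured_positive / result.n_targeted


def efficiency_slope(results: list[CaptureResult],
                     through_origin: bool = False) -> tuple[float, float]:
    """Least-squares slope of captured positives vs targeted cells.

    Ordinary least squares with a free intercept by default (a slope of 1
    means loss-free capture across experiment sizes); ``through_origin``
    forces the fit through (0, 0) and returns intercept 0.
    """
    x = np.array([r.n_targeted for r in results], dtype=float)
    y = np.array([r.n_captured_positive for r in results], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct n_targeted values for a fit")
    if through_origin:
        return float(x.dot(y) / x.dot(x)), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def purity(result: CaptureResult) -> tuple[float, float]:
    """(purity, contamination) among all captured cells.

    Accepts non-integer counts so averaged experiment series can be used
    directly.
    """
    total = result.n_captured_positive + result.n_captured_negative
    if total <= 0:
        raise ValueError("purity undefined: no captured cells")
    p = result.n_captured_positive / total
    return p, 1.0 - p


def enrichment(initial_positive_fraction: float,
               final_positive_fraction: float) -> tuple[float, float]:
    """Fold enrichment and its order of magnitude (log10)."""
    if not (0.0 < initial_positive_fraction <= 1.0):
        raise ValueError("initial fraction must lie in (0, 1]")
    if not (0.0 < final_positive_fraction <= 1.0):
        raise ValueError("final fraction must lie in (0, 1]")
    fold = final_positive_fraction / initial_positive_fraction
    return fold, float(np.log10(fold))


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _find_all(template: str, site: str) -> list[int]:
    out, i = [], template.find(site)
    while i != -1:
        out.append(i)
        i = template.find(site, i + 1)
    return out


def _scan_one_strand(template: str, forward: str, reverse: str,
                     max_length: int) -> list[int]:
    rc_rev = reverse_complement(reverse)
    f_sites = _find_all(template, forward)
    r_sites = _find_all(template, rc_rev)
    out = []
    for i in f_sites:
        for j in r_sites:
            if j >= i:
                length = j + len(rc_rev) - i
                if max(len(forward), len(rc_rev)) <= length <= max_length:
                    out.append(length)
    return out


def insilico_pcr(pair, template: str, max_length: int = 5000) -> list[int]:
    """Exact-match in-silico PCR: amplicon lengths for a primer pair.

    The template is scanned for exact occurrences of the forward primer
    followed (downstream) by the reverse complement of the reverse primer;
    the product length spans both primer footprints inclusively. Both
    template strands are scanned; products longer than ``max_length`` are
    discarded. No site pair yields an empty list, not an error.

    ``pair`` is a :class:`PrimerPair` or a plain ``(forward, reverse)``
    tuple (the tuple form skips primer-length validation).
    """
    if isinstance(pair, PrimerPair):
        fwd, rev = pair.forward, pair.reverse
    else:
        fwd, rev = (s.upper() for s in pair)
    template = "".join(template.split()).upper()
    if not re.match(r"^[ACGTN]*$", template):
        raise ValueError("template must contain only A/C/G/T/N")
    lengths = _scan_one_strand(template, fwd, rev, max_length)
    lengths += _scan_one_strand(reverse_complement(template), fwd, rev, max_length)
    return sorted(lengths)


# ---------------------------------------------------------------------------
# bundled stand-in templates
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Minimal single/multi-record FASTA reader (plain text)."""
    records: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = ""
            elif name is not None:
                records[name] += line.upper()
    return records


def load_standin_templates() -> dict[str, str]:
    """Bundled SYNTHETIC cytochrome-b stand-in templates.

    These are not the real dog or mouse mitochondrial sequences: they are
    synthetic templates in which the printed primer footprints are planted
    at the spacing that yields the known species-specific product sizes
    (247 nt for the dog pair, 196 nt for the mouse pair). They exercise the
    in-silico PCR engine and its inclusive product-length convention; for a
    genuine species check, run :func:`insilico_pcr` against the authentic
    mitochondrial sequences.
    """
    out = {}
    for fname, key in (("cytb_dog_standin_synthetic.fasta", "dog"),
                       ("cytb_mouse_standin_synthetic.fasta", "mouse")):
        path = resources.files("focikit.data").joinpath(fname)
        rec = read_fasta(path)
        out[key] = next(iter(rec.values()))
    return out
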