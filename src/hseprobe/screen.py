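"""Flanking-sequence specificity screen.

Counts near-exact probe binding sites in the sequence surrounding the
extraction locus (default window +/- 50 kb, the maximum distance at which
successful extraction has been scored).  A site only matters for
allele-specific extension if the polymerase can extend it, so hits are split
into 3'-anchored (the probe's last ``anchor_len`` bases perfectly paired —
extendable) and 3'-mismatched (annealing-only).  Scoring is count-based:
positions with at most ``max_mismatches`` differences on either strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .probes import ProbeSpec
from .thermo import reverse_complement

__all__ = ["Hit", "HitReport", "scan", "g_run_warning"]

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_ANCHOR_LEN = 3
DEFAULT_WINDOW_KB = 50.0


@dataclass(frozen=True)
class Hit:
    """One candidate binding site on the scanned sequence.

    ``position`` is the 0-based forward-strand start of the site;
    ``strand`` "+" means the probe sequence matches the forward strand
    (anneals to the reverse strand), "-" the opposite.
    """

    position: int
    strand: str
    mismatch_count: int
    three_prime_matched: bool
    distance_kb: float
    is_design_site: bool = False


@dataclass
class HitReport:
    set_name: str
    probe_length: int
    hits: list[Hit]
    max_mismatches: int
    anchor_len: int
    warnings: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        n_ext = sum(1 for h in self.hits if h.three_prime_matched)
        return {
            "n_hits": len(self.hits),
            "n_extendable": n_ext,
            "n_three_prime_mismatched": len(self.hits) - n_ext,
            "n_off_target": sum(1 for h in self.hits if not h.is_design_site),
        }


def g_run_warning(sequence: str, run_len: int = 3) -> str | None:
    """Promiscuity warning for low-complexity probes with runs of guanosines."""
    if re.search("G" * run_len, sequence.upper()):
        return (f"probe contains a run of >= {run_len} consecutive G; such "
                "low-complexity probes tend to mishybridize")
    return None


def _mismatch_profile(seq_arr: np.ndarray, probe_arr: np.ndarray) -> np.ndarray:
    """Per-offset mismatch counts of probe_arr against every window of seq_arr."""
    n, L = seq_arr.size, probe_arr.size
    if n < L:
        raise ValueError("scan window shorter than the probe")
    counts = np.zeros(n - L + 1, dtype=np.int32)
    for j in range(L):
        counts += seq_arr[j : j + counts.size] != probe_arr[j]
    return counts


def scan(
    probe: ProbeSpec | str,
    flank_seq: str,
    locus_pos: int,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    three_prime_anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_distance_kb: float | None = DEFAULT_WINDOW_KB,
) -> HitReport:
    """Slide the probe over both strands of ``flank_seq`` and report hits.

    ``locus_pos`` is the extraction-locus (SNP) position in ``flank_seq``,
    used for hit distances and for labelling the design site itself.  Hits
    farther than ``max_distance_kb`` from the locus are dropped unless the
    window limit is disabled with None.
    """
    if isinstance(probe, ProbeSpec):
        pseq, name = probe.sequence, probe.set_name
    else:
        pseq, name = str(probe).upper(), "probe"
    seq = flank_seq.upper()
    L = len(pseq)
    if len(seq) < L:
        raise ValueError("scan window shorter than the probe")
    if three_prime_anchor_len > L:
        raise ValueError("anchor length exceeds probe length")

    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits: list[Hit] = []

    # "+" strand: probe sequence equals the forward sequence at the site.
    plus = np.frombuffer(pseq.encode(), dtype=np.uint8)
    counts = _mismatch_profile(seq_arr, plus)
    anchor = np.ones(counts.size, dtype=bool)
    for j in range(L - three_prime_anchor_len, L):
        anchor &= seq_arr[j : j + counts.size] == plus[j]
    for pos in np.flatnonzero(counts <= max_mismatches):
        hits.append(_make_hit(int(pos), "+", int(counts[pos]), bool(anchor[pos]),
                              locus_pos, L))

    # "-" strand: reverse-complement of the probe appears in the forward
    # sequence; the probe 3' end maps to the site's forward-strand start.
    minus = np.frombuffer(reverse_complement(pseq).encode(), dtype=np.uint8)
    counts = _mismatch_profile(seq_arr, minus)
    anchor = np.ones(counts.size, dtype=bool)
    for j in range(three_prime_anchor_len):
        anchor &= seq_arr[j : j + counts.size] == minus[j]
    for pos in np.flatnonzero(counts <= max_mismatches):
        hits.append(_make_hit(int(pos), "-", int(counts[pos]), bool(anchor[pos]),
                              locus_pos, L))

    if max_distance_kb is not None:
        hits = [h for h in hits if h.distance_kb <= max_distance_kb]
    hits.sort(key=lambda h: (h.position, h.strand))

    warnings = []
    w = g_run_warning(pseq)
    if w:
        warnings.append(w)
    return HitReport(name, L, hits, max_mismatches, three_prime_anchor_len, warnings)


def _make_hit(pos: int, strand: str, mm: int, anchored: bool, locus_pos: int,
              length: int) -> Hit:
    covers_locus = pos <= locus_pos < pos + length
    distance = 0.0 if covers_locus else min(abs(pos - locus_pos),
                                            abs(pos + length - 1 - locus_pos)) / 1000.0
    return Hit(pos, strand, mm, anchored, distance,
               is_design_site=covers_locus and mm == 0)
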