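"""Probe-length series, the match-minus-mismatch duplex-concentration curve,
and the G/C-content-vs-optimal-length linear model.

A "probe set" is every 5'-truncation length variant of one allele-specific
design (locus + orientation + discriminating base + discriminator position).
The probe's 3' terminus sits on the SNP (offset 0) or one base past it
(penultimate, offset 1).  The specificity predictor is Delta-con_M-MM: the
difference between the equilibrium duplex concentration of the probe bound
to its matched target and to the single-mismatch target at assay conditions;
the optimal probe length is the argmax of that curve over the series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from . import thermo
from .thermo import DuplexParams, NNParameterSet, complement, reverse_complement

__all__ = [
    "ProbeSpec",
    "DeltaConCurve",
    "GcLengthModel",
    "enumerate_probes",
    "build_mismatch_target",
    "delta_con_curve",
    "predict_best_length",
    "fit_gc_length_model",
]

logger = logging.getLogger(__name__)

#: Plateau: lengths whose delta-con is within this fraction of the maximum.
DEFAULT_PLATEAU_TOL = 0.10
#: No-discrimination floor as a fraction of the per-allele target concentration.
DEFAULT_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class ProbeSpec:
    """One oligonucleotide probe within a named probe set.

    ``sequence`` is 5'->3' on the probe's own strand.  ``matched_allele`` is
    the probe-strand base at the discriminator (for reverse-orientation
    probes this is the complement of the forward-reference allele).
    ``mismatch_pair`` is (probe base, mismatched target base), the order used
    in the published probe tables.  ``ref_interval`` locates the probe on the
    forward reference strand as a 0-based half-open interval when known.
    """

    set_name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    discriminator_offset: int  # 0 = 3' terminus, 1 = penultimate
    matched_allele: str
    mismatch_pair: tuple[str, str] | None = None
    ref_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 6:
            raise ValueError("probe shorter than 6 nt")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.discriminator_offset not in (0, 1):
            raise ValueError("discriminator_offset must be 0 (3') or 1 (penultimate)")
        disc = seq[self.discriminator_index]
        if disc != self.matched_allele.upper():
            raise ValueError(
                f"probe base {disc} at the discriminator position does not "
                f"match the design allele {self.matched_allele}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def discriminator_index(self) -> int:
        return self.length - 1 - self.discriminator_offset

    @property
    def matched_target_site(self) -> str:
        """Template strand written 3'->5', aligned under the probe."""
        return complement(self.sequence)

    def trimmed(self, length: int) -> "ProbeSpec":
        """The 5'-truncated variant of this probe at the given length."""
        if not (6 <= length <= self.length):
            raise ValueError(f"cannot trim length-{self.length} probe to {length}")
        interval = None
        if self.ref_interval is not None:
            start, end = self.ref_interval
            interval = (end - length, end) if self.orientation == "forward" else (start, start + length)
        return ProbeSpec(
            self.set_name, self.sequence[-length:], self.orientation,
            self.discriminator_offset, self.matched_allele, self.mismatch_pair,
            interval,
        )


def enumerate_probes(
    locus_seq: str,
    snp_pos: int,
    allele: str,
    orientation: str = "forward",
    discriminator_offset: int = 0,
    length_range: range | tuple[int, int] = (9, 25),
    locus_name: str = "locus",
) -> list[ProbeSpec]:
    """Build the 5'-trim length series of one probe design.

    ``allele`` is the forward-reference-strand base the probe must match;
    reverse-orientation probes carry its complement at their discriminator.
    Forward probes end 3' at the SNP (offset 0) or one base past it
    (offset 1); successive lengths differ only by 5' truncation.
    Coordinates are 0-based on the forward strand.
    """
    seq = locus_seq.upper()
    allele = allele.upper()
    if not (0 <= snp_pos < len(seq)):
        raise ValueError("snp_pos outside the locus sequence")
    if isinstance(length_range, range):
        lengths = sorted(length_range)
    else:
        lo, hi = length_range
        lengths = list(range(lo, hi + 1))
    if not lengths or lengths[0] < 6 or lengths[-1] > 40:
        raise ValueError("length range must lie within [6, 40]")
    off = discriminator_offset
    if off not in (0, 1):
        raise ValueError("discriminator_offset must be 0 or 1")

    probes = []
    for length in lengths:
        if orientation == "forward":
            end = snp_pos + 1 + off  # 3' end one past the SNP for -1 designs
            start = end - length
            if start < 0 or end > len(seq):
                raise ValueError(f"SNP too close to the sequence end for length {length}")
            probe_seq = seq[start:end]
            idx = snp_pos - start
            probe_seq = probe_seq[:idx] + allele + probe_seq[idx + 1 :]
            probe_allele = allele
        elif orientation == "reverse":
            start = snp_pos - off
            end = start + length
            if start < 0 or end > len(seq):
                raise ValueError(f"SNP too close to the sequence end for length {length}")
            top = seq[start:end]
            idx = snp_pos - start
            top = top[:idx] + allele + top[idx + 1 :]
            probe_seq = reverse_complement(top)
            probe_allele = complement(allele)
        else:
            raise ValueError("orientation must be 'forward' or 'reverse'")
        name = (
            f"{locus_name}{'F' if orientation == 'forward' else 'R'}{probe_allele}"
            + ("-1" if off else "")
        )
        probes.append(
            ProbeSpec(name, probe_seq, orientation, off, probe_allele,
                      ref_interval=(start, end))
        )
    return probes


def build_mismatch_target(probe: ProbeSpec, other_allele: str) -> str:
    """Target site (3'->5', aligned under the probe) for the other allele.

    Identical to the matched template except at the SNP: the template base
    becomes the other allele's template-strand base, producing the single
    defined mismatch opposite the probe's discriminator.
    """
    other = other_allele.upper()
    fwd_matched = (
        probe.matched_allele if probe.orientation == "forward"
        else complement(probe.matched_allele)
    )
    if other == fwd_matched:
        raise ValueError("other_allele equals the design allele; no mismatch to build")
    # Forward probes anneal to the bottom strand (template base = complement of
    # the forward allele); reverse probes anneal to the top strand directly.
    target_base = complement(other) if probe.orientation == "forward" else other
    site = probe.matched_target_site
    i = probe.discriminator_index
    if target_base == site[i]:
        raise ValueError("alleles are complementary on opposite strands; no mismatch arises")
    return site[:i] + target_base + site[i + 1 :]


@dataclass
class DeltaConCurve:
    """Per-length match/mismatch duplex concentrations for one probe set.

    ``rows`` holds (length, con_M, con_MM, delta_con) in molar; the curve is
    reported in units of 1e-17 M by the TSV writer.  ``best_length`` is the
    argmax of delta_con with ties broken toward the shorter probe;
    ``best_lengths_plateau`` lists every length within the plateau tolerance
    of the maximum.  ``no_discrimination`` flags curves whose maximum
    delta-con is below the floor (mismatch as stable as the match).
    """

    set_name: str
    rows: list[tuple[int, float, float, float]]
    best_length: int
    best_lengths_plateau: list[int]
    conditions: DuplexParams
    no_discrimination: bool = False
    note: str = ""

    def delta_con(self, length: int) -> float:
        for l, _, _, d in self.rows:
            if l == length:
                return d
        raise KeyError(length)

    @property
    def max_delta_con(self) -> float:
        return max(d for _, _, _, d in self.rows)

    def is_unimodal(self, tol: float = DEFAULT_PLATEAU_TOL) -> bool:
        """Single plateau: lengths within tolerance of the maximum are contiguous."""
        if not self.best_lengths_plateau:
            return True
        plateau = sorted(self.best_lengths_plateau)
        lengths = sorted(l for l, _, _, _ in self.rows)
        i, j = lengths.index(plateau[0]), lengths.index(plateau[-1])
        return lengths[i : j + 1] == plateau


def delta_con_curve(
    probe_series: list[ProbeSpec],
    other_allele: str | None = None,
    params: DuplexParams | None = None,
    nn_params: NNParameterSet | None = None,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    mismatch_target_base: str | None = None,
) -> DeltaConCurve:
    """Simulate con_M, con_MM and their difference across a 5'-trim series.

    The mismatched template base is derived from ``other_allele`` (forward
    reference strand) or given directly as ``mismatch_target_base`` when only
    the probe sequence and its printed mismatch are known.
    """
    params = params or DuplexParams()
    if len(probe_series) < 3:
        raise ValueError("need at least 3 probe lengths")
    names = {p.set_name for p in probe_series}
    if len(names) != 1:
        raise ValueError(f"probes from multiple sets: {sorted(names)}")
    series = sorted(probe_series, key=lambda p: p.length)

    rows = []
    for probe in series:
        match_site = probe.matched_target_site
        if mismatch_target_base is not None:
            i = probe.discriminator_index
            if mismatch_target_base.upper() == match_site[i]:
                raise ValueError("mismatch_target_base equals the matched template base")
            mm_site = match_site[:i] + mismatch_target_base.upper() + match_site[i + 1 :]
        elif other_allele is not None:
            mm_site = build_mismatch_target(probe, other_allele)
        else:
            raise ValueError("provide other_allele or mismatch_target_base")
        try:
            con_m = thermo.simulate_pairing(probe.sequence, match_site, params, nn_params).duplex_conc_molar
            con_mm = thermo.simulate_pairing(probe.sequence, mm_site, params, nn_params).duplex_conc_molar
        except Exception as exc:
            raise type(exc)(f"{probe.set_name} length {probe.length}: {exc}") from exc
        rows.append((probe.length, con_m, con_mm, con_m - con_mm))

    max_d = max(d for _, _, _, d in rows)
    floor = floor_fraction * params.target_conc_molar
    no_disc = max_d < floor
    plateau = [l for l, _, _, d in rows if d >= (1.0 - plateau_tol) * max_d] if not no_disc else []
    best = min((l for l, _, _, d in rows if d == max_d), default=rows[0][0])
    note = ""
    if no_disc:
        note = (f"no-discrimination: max delta-con {max_d:.3g} M below floor "
                f"{floor:.3g} M (mismatch as stable as the match)")
        logger.info("%s: %s", series[0].set_name, note)
    return DeltaConCurve(series[0].set_name, rows, best, plateau, params, no_disc, note)


def predict_best_length(curve: DeltaConCurve) -> tuple[int, list[int], str]:
    """(best_length, plateau, note) — argmax with ties broken toward shorter.

    A no-discrimination curve keeps its argmax but the note flags that no
    confident optimum exists.
    """
    if not curve.rows:
        raise ValueError("empty curve")
    note = curve.note
    if len(curve.best_lengths_plateau) > 1 and not note:
        note = f"near-tie plateau {curve.best_lengths_plateau}; shortest maximal length reported"
        logger.info("%s: %s", curve.set_name, note)
    return curve.best_length, curve.best_lengths_plateau, note


@dataclass
class GcLengthModel:
    """Linear model of optimal probe length as a function of G/C content.

    Higher G/C means stronger stacks, so the duplex-concentration optimum is
    reached at shorter lengths: the fitted slope is negative (nt per G/C
    percentage point).
    """

    slope: float
    intercept: float
    fit_points: list[tuple[float, float, str]]
    residuals: np.ndarray
    rsquared: float

    def predict(self, gc_percent: float) -> int:
        """Optimal probe length (nt, rounded to the nearest integer)."""
        return int(round(self.intercept + self.slope * gc_percent))

    def predict_exact(self, gc_percent) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(gc_percent, dtype=float)


def fit_gc_length_model(
    points: list[tuple[float, float]] | list[tuple[float, float, str]],
) -> GcLengthModel:
    """Ordinary least squares of optimal length on G/C percentage."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    tagged = [(p[0], p[1], p[2] if len(p) > 2 else "experimental") for p in points]
    gc = np.array([p[0] for p in tagged], dtype=float)
    length = np.array([p[1] for p in tagged], dtype=float)
    if np.unique(gc).size < 2:
        raise ValueError("degenerate design: all G/C values identical")
    res = sm.OLS(length, sm.add_constant(gc)).fit()
    intercept, slope = res.params
    model = GcLengthModel(slope, intercept, tagged, np.asarray(res.resid), res.rsquared)
    if slope >= 0:
        logger.warning("fitted G/C-length slope %.3f is non-negative; expected "
                       "shorter optima at higher G/C", slope)
    return model
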