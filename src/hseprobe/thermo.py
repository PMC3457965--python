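"""Nearest-neighbor DNA duplex thermodynamics.

Two-state model for short probe/target hetero-duplexes: enthalpy and entropy
are sums of published dinucleotide stack parameters plus initiation terms;
a single mismatch at the probe 3' terminus uses terminal-mismatch stack
parameters, a mismatch at the penultimate (-1) position uses internal-mismatch
parameters for its two flanking stacks.  From (dH, dS) the module derives the
free energy at assay temperature, a concentration-dependent melting
temperature, and the equilibrium duplex concentration of P + T <=> PT.

Units: dH kcal/mol, dS cal/(mol K), dG kcal/mol, concentrations molar,
temperatures Celsius at the API surface and Kelvin internally.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "R_CAL",
    "NNParameterSet",
    "DuplexParams",
    "ThermoResult",
    "MissingParameterError",
    "complement",
    "reverse_complement",
    "gc_content",
    "duplex_energy",
    "salt_corrected_entropy",
    "melting_temperature",
    "duplex_concentration",
    "melting_curve",
    "simulate_pairing",
]

logger = logging.getLogger(__name__)

#: Gas constant in cal/(mol K).
R_CAL = 1.987

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class MissingParameterError(KeyError):
    """A dinucleotide opposition has no entry in the loaded parameter set."""


class UnsupportedGeometryError(ValueError):
    """Mismatch placement outside the supported 3'-terminal / penultimate designs."""


def _clean(seq: str, what: str = "sequence") -> str:
    s = str(seq).upper()
    if not s:
        raise ValueError(f"empty {what}")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT characters {sorted(bad)} "
            "(IUPAC ambiguity codes are not supported)"
        )
    return s


def complement(seq: str) -> str:
    """Base-wise complement (no reversal)."""
    return _clean(seq).translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def gc_content(sequence: str) -> float:
    """G+C percentage of a DNA sequence (exact value; round only for display)."""
    s = _clean(sequence)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------

def _is_wc(top: str, bottom: str) -> bool:
    return bottom == top.translate(_COMPLEMENT)


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor stack parameters at the 1 M NaCl reference condition.

    Keys are ``"XY/WZ"``: top strand 5'->3' dinucleotide, ``/``, the opposing
    bottom strand dinucleotide written 3'->5' (so X pairs W, Y pairs Z).
    The 10-entry Watson-Crick table is closed under reading the duplex from
    the other strand; lookups try the key and its other-strand equivalent and
    raise :class:`MissingParameterError` rather than returning zero.
    """

    wc_params: dict[str, tuple[float, float]]
    mismatch_params: dict[str, tuple[float, float]]
    terminal_mismatch_params: dict[str, tuple[float, float]]
    initiation: dict[str, tuple[float, float]]
    symmetry: tuple[float, float] = (0.0, -1.4)
    source_label: str = ""

    @classmethod
    def from_csv(cls, path=None) -> "NNParameterSet":
        """Load the packaged (or a user-supplied) parameter CSV."""
        if path is None:
            ref = resources.files("hseprobe.data") / "nn_params_santalucia.csv"
            text = ref.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        wc: dict[str, tuple[float, float]] = {}
        imm: dict[str, tuple[float, float]] = {}
        tmm: dict[str, tuple[float, float]] = {}
        init: dict[str, tuple[float, float]] = {}
        sym = (0.0, 0.0)
        sources: list[str] = []
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        for row in csv.DictReader(lines):
            val = (float(row["dh_kcal"]), float(row["ds_cal"]))
            kind, key = row["kind"], row["key"]
            if kind == "wc":
                wc[key] = val
            elif kind == "internal_mm":
                imm[key] = val
            elif kind == "terminal_mm":
                tmm[key] = val
            elif kind == "initiation":
                init[key] = val
            elif kind == "symmetry":
                sym = val
            else:
                raise ValueError(f"unknown parameter kind {kind!r}")
            if row["source"] not in sources:
                sources.append(row["source"])
        ps = cls(wc, imm, tmm, init, sym, source_label="; ".join(sources))
        ps.validate()
        return ps

    def validate(self) -> None:
        for key, (dh, _) in self.wc_params.items():
            if dh >= 0:
                raise ValueError(f"Watson-Crick stack {key} has non-negative dH")
            alt = key[::-1]
            if alt in self.wc_params and self.wc_params[alt] != self.wc_params[key]:
                raise ValueError(f"WC table not closed under strand swap at {key}")

    def _lookup(self, table: dict, key: str, label: str) -> tuple[float, float]:
        # "XY/WZ" read from the other strand is "ZW/YX" == key[::-1]
        if key in table:
            return table[key]
        if key[::-1] in table:
            return table[key[::-1]]
        raise MissingParameterError(f"no {label} parameters for stack {key}")

    def stack(self, top: str, bottom: str) -> tuple[float, float]:
        """(dH, dS) for one dinucleotide doublet; dispatches WC vs internal mismatch."""
        key = f"{top}/{bottom}"
        if _is_wc(top, bottom):
            return self._lookup(self.wc_params, key, "Watson-Crick")
        return self._lookup(self.mismatch_params, key, "internal-mismatch")

    def terminal_stack(self, top: str, bottom: str) -> tuple[float, float]:
        """(dH, dS) for the doublet closing a 3'-terminal mismatch (mismatch on
        the right of the top strand as written)."""
        key = f"{top}/{bottom}"
        if key in self.terminal_mismatch_params:
            return self.terminal_mismatch_params[key]
        raise MissingParameterError(f"no terminal-mismatch parameters for stack {key}")

    def initiation_for(self, probe_base: str) -> tuple[float, float]:
        key = "init_A/T" if probe_base in "AT" else "init_G/C"
        try:
            return self.initiation[key]
        except KeyError as exc:  # pragma: no cover - malformed custom table
            raise MissingParameterError(f"missing initiation term {key}") from exc


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_parameter_set() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = NNParameterSet.from_csv()
    return _DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# Assay conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplexParams:
    """Assay conditions for the hybridization simulation.

    Defaults reflect the modelled extraction assay: hybridization at 64 C,
    probe in vast excess (5 uM) over per-allele genomic target (3 fM,
    i.e. a few hundred ng of genomic DNA in a 30 ul reaction split between
    two contributors), 50 mM monovalent salt and 1.5 mM Mg.
    """

    temperature_celsius: float = 64.0
    probe_conc_molar: float = 5e-6
    target_conc_molar: float = 3e-15
    monovalent_molar: float = 0.05
    magnesium_molar: float = 1.5e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature_celsius <= 100.0):
            raise ValueError("temperature must be in [0, 100] C")
        if self.probe_conc_molar <= 0 or self.target_conc_molar <= 0:
            raise ValueError("strand concentrations must be positive")
        if self.monovalent_molar <= 0:
            raise ValueError("monovalent salt must be positive")
        if self.magnesium_molar < 0:
            raise ValueError("magnesium must be non-negative")
        if self.probe_conc_molar < self.target_conc_molar:
            logger.warning(
                "probe concentration %.3g M below target %.3g M; the modelled "
                "regime is probe in vast excess",
                self.probe_conc_molar,
                self.target_conc_molar,
            )

    @property
    def temperature_kelvin(self) -> float:
        return self.temperature_celsius + 273.15

    @property
    def sodium_equivalent_molar(self) -> float:
        """Monovalent Na+-equivalent including the divalent contribution
        (120 * sqrt([Mg2+] in mM), von Ahsen-style)."""
        return self.monovalent_molar + 3.795 * math.sqrt(self.magnesium_molar)


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic summary for one probe/target pairing at given conditions."""

    delta_h: float
    delta_s: float
    delta_g_at_t: float
    tm_celsius: float | None
    duplex_conc_molar: float
    pairing_kind: str  # match | terminal_mismatch | internal_mismatch_penultimate


# ---------------------------------------------------------------------------
# Energy summation
# ---------------------------------------------------------------------------

def _mismatch_positions(probe: str, target: str) -> list[int]:
    return [i for i, (p, t) in enumerate(zip(probe, target)) if t != p.translate(_COMPLEMENT)]


def duplex_energy(
    probe_seq: str,
    target_site: str,
    params: NNParameterSet | None = None,
) -> tuple[float, float]:
    """Sum nearest-neighbor (dH, dS) for a probe/target duplex.

    ``probe_seq`` is 5'->3'; ``target_site`` is the opposing strand written
    3'->5' and aligned base-for-base under the probe.  At most one mismatch is
    allowed and it must sit at the probe 3' terminus or the penultimate
    position — the two geometries used by allele-discriminating extension
    probes.  Returns (dH kcal/mol, dS cal/(mol K)) at 1 M NaCl.
    """
    params = params or default_parameter_set()
    probe = _clean(probe_seq, "probe")
    target = _clean(target_site, "target site")
    if len(probe) != len(target):
        raise ValueError("probe and target site must have equal length")
    n = len(probe)
    if n < 2:
        raise ValueError("duplex must be at least 2 bp")
    mispos = _mismatch_positions(probe, target)
    if len(mispos) > 1:
        raise UnsupportedGeometryError(f"{len(mispos)} mismatches; at most one supported")
    terminal_mm = mispos == [n - 1]
    penultimate_mm = mispos == [n - 2]
    if mispos and not (terminal_mm or penultimate_mm):
        raise UnsupportedGeometryError(
            f"mismatch at position {mispos[0]} unsupported; only the 3' terminus "
            f"({n - 1}) or penultimate ({n - 2}) position is modelled"
        )

    dh = ds = 0.0
    # Stacks. A 3'-terminal mismatch consumes its single flanking stack from
    # the terminal-mismatch table; everything else zips through stack().
    last_stack = n - 2
    for i in range(n - 1):
        top, bottom = probe[i : i + 2], target[i : i + 2]
        if terminal_mm and i == last_stack:
            h, s = params.terminal_stack(top, bottom)
        else:
            h, s = params.stack(top, bottom)
        dh += h
        ds += s
    # Initiation per duplex end, assigned by the probe-strand terminal base.
    for base in (probe[0], probe[-1]):
        h, s = params.initiation_for(base)
        dh += h
        ds += s
    if not mispos and probe == reverse_complement(probe):
        h, s = params.symmetry
        dh += h
        ds += s
    return dh, ds


def pairing_kind(probe_seq: str, target_site: str) -> str:
    probe = _clean(probe_seq, "probe")
    target = _clean(target_site, "target site")
    mispos = _mismatch_positions(probe, target)
    if not mispos:
        return "match"
    if mispos == [len(probe) - 1]:
        return "terminal_mismatch"
    if mispos == [len(probe) - 2]:
        return "internal_mismatch_penultimate"
    raise UnsupportedGeometryError("unsupported mismatch geometry")


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def salt_corrected_entropy(
    delta_s: float, n_phosphates: int, params: DuplexParams
) -> float:
    """Entropic salt correction: dS + 0.368 * N * ln[Na+ equivalent].

    ``n_phosphates`` is the per-strand phosphate count (duplex length - 1).
    Identity at the tables' 1 M Na+ reference condition with no Mg.
    """
    na_eq = params.sodium_equivalent_molar
    if na_eq <= 0:
        raise ValueError("non-positive salt")
    return delta_s + 0.368 * n_phosphates * math.log(na_eq)


def free_energy(delta_h: float, delta_s: float, t_kelvin: float) -> float:
    """dG (kcal/mol) = dH - T * dS / 1000."""
    return delta_h - t_kelvin * delta_s / 1000.0


def melting_temperature(
    delta_h: float,
    delta_s: float,
    probe_conc: float,
    target_conc: float,
) -> float | None:
    """Two-state hetero-duplex Tm (Celsius) with the CT/4 convention.

    ``delta_s`` should already be salt-corrected.  Returns None when the
    denominator is non-positive (no two-state melting temperature).
    """
    if probe_conc <= 0 or target_conc <= 0:
        raise ValueError("strand concentrations must be positive")
    ct = probe_conc + target_conc
    denom = delta_s + R_CAL * math.log(ct / 4.0)
    if denom >= 0:
        return None
    return 1000.0 * delta_h / denom - 273.15


def duplex_concentration(
    delta_g_at_t: float,
    probe_conc: float,
    target_conc: float,
    t_kelvin: float,
) -> float:
    """Equilibrium [PT] for P + T <=> PT with K = exp(-dG*1000/(R T)).

    Solves K x^2 - (1 + K (P0 + T0)) x + K P0 T0 = 0 for the physical
    (smaller) root in the numerically stable form
    x = 2 K P0 T0 / (b + sqrt(b^2 - 4 K^2 P0 T0)), b = 1 + K (P0 + T0),
    valid for K P0 from far below to far above 1.
    """
    if probe_conc <= 0 or target_conc <= 0:
        raise ValueError("strand concentrations must be positive")
    lnk = -delta_g_at_t * 1000.0 / (R_CAL * t_kelvin)
    # K beyond float range: the bound min(P0, T0) (K -> inf) or 0 (K -> 0).
    if lnk > 700.0:
        return min(probe_conc, target_conc)
    if lnk < -700.0:
        return 0.0
    k = math.exp(lnk)
    b = 1.0 + k * (probe_conc + target_conc)
    # rounding can push the discriminant marginally negative when the two
    # roots coincide (huge K with P0 == T0)
    disc = max(b * b - 4.0 * k * k * probe_conc * target_conc, 0.0)
    x = 2.0 * k * probe_conc * target_conc / (b + math.sqrt(disc))
    return min(max(x, 0.0), min(probe_conc, target_conc))


def melting_curve(
    probe_seq: str,
    target_site: str,
    params: DuplexParams | None = None,
    t_range: Sequence[float] | None = None,
    nn_params: NNParameterSet | None = None,
) -> np.ndarray:
    """Duplex concentration versus temperature: array of (temp C, [PT] molar).

    The two-state curve is monotone non-increasing in temperature, with a
    low-temperature plateau at min(P0, T0) once binding saturates.
    """
    params = params or DuplexParams()
    if t_range is None:
        t_range = np.arange(0.0, 100.5, 1.0)
    temps = np.asarray(list(t_range), dtype=float)
    if temps.size == 0:
        raise ValueError("empty temperature range")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature range must be strictly ascending")
    dh, ds = duplex_energy(probe_seq, target_site, nn_params)
    ds_corr = salt_corrected_entropy(ds, len(probe_seq) - 1, params)
    out = np.empty((temps.size, 2), dtype=float)
    for i, tc in enumerate(temps):
        tk = tc + 273.15
        dg = free_energy(dh, ds_corr, tk)
        out[i] = (tc, duplex_concentration(dg, params.probe_conc_molar,
                                           params.target_conc_molar, tk))
    return out


def simulate_pairing(
    probe_seq: str,
    target_site: str,
    params: DuplexParams | None = None,
    nn_params: NNParameterSet | None = None,
) -> ThermoResult:
    """Full two-state summary for one probe/target pairing at assay conditions."""
    params = params or DuplexParams()
    kind = pairing_kind(probe_seq, target_site)
    dh, ds = duplex_energy(probe_seq, target_site, nn_params)
    ds_corr = salt_corrected_entropy(ds, len(probe_seq) - 1, params)
    tk = params.temperature_kelvin
    dg = free_energy(dh, ds_corr, tk)
    tm = melting_temperature(dh, ds_corr, params.probe_conc_molar,
                             params.target_conc_molar)
    conc = duplex_concentration(dg, params.probe_conc_molar,
                                params.target_conc_molar, tk)
    return ThermoResult(dh, ds_corr, dg, tm, conc, kind)
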