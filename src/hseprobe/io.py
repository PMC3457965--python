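"""Formats and configuration: FASTA input, TSV/report output, run config.

Conventions: sequences normalized to uppercase; coordinates 0-based
half-open on the forward strand; duplex concentrations written in units of
1e-17 M (molar internally); one YAML-serializable config object with no
hidden defaults scattered through the code.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .thermo import DuplexParams, gc_content
from .probes import (DEFAULT_FLOOR_FRACTION, DEFAULT_PLATEAU_TOL,
                     DeltaConCurve, ProbeSpec)
from . import thermo

__all__ = ["RunConfig", "read_fasta", "curve_table", "write_curve_tsv",
           "write_report"]

logger = logging.getLogger(__name__)

CON_UNIT = 1e-17  # reporting unit for duplex concentrations


@dataclass
class RunConfig:
    """Serializable run configuration covering all tunable defaults."""

    temperature_celsius: float = 64.0
    probe_conc_molar: float = 5e-6
    target_conc_molar: float = 3e-15
    monovalent_molar: float = 0.05
    magnesium_molar: float = 1.5e-3
    min_length: int = 9
    max_length: int = 25
    plateau_tol: float = DEFAULT_PLATEAU_TOL
    floor_fraction: float = DEFAULT_FLOOR_FRACTION
    max_mismatches: int = 2
    three_prime_anchor_len: int = 3
    window_kb: float = 50.0
    seed: int = 0
    output_dir: str = "."

    def duplex_params(self) -> DuplexParams:
        return DuplexParams(self.temperature_celsius, self.probe_conc_molar,
                            self.target_conc_molar, self.monovalent_molar,
                            self.magnesium_molar)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as {id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def curve_table(curve: DeltaConCurve, probes: list[ProbeSpec]) -> pd.DataFrame:
    """Per-length TSV-ready table mirroring the published series layout."""
    by_len = {p.length: p for p in probes}
    params = curve.conditions
    rows = []
    for length, con_m, con_mm, delta in curve.rows:
        probe = by_len[length]
        res = thermo.simulate_pairing(probe.sequence, probe.matched_target_site,
                                      params)
        flags = []
        if length == curve.best_length:
            flags.append("best")
        elif length in curve.best_lengths_plateau:
            flags.append("plateau")
        if curve.no_discrimination:
            flags.append("no-discrimination")
        rows.append({
            "length": length,
            "sequence": probe.sequence,
            "gc_pct": round(gc_content(probe.sequence)),
            "tm_c": None if res.tm_celsius is None else round(res.tm_celsius, 1),
            "dg_kcal": round(res.delta_g_at_t, 2),
            "con_M_1e17": con_m / CON_UNIT,
            "con_MM_1e17": con_mm / CON_UNIT,
            "delta_con_1e17": delta / CON_UNIT,
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)


def write_curve_tsv(curve: DeltaConCurve, probes: list[ProbeSpec], path) -> None:
    df = curve_table(curve, probes)
    with open(path, "w") as fh:
        p = curve.conditions
        fh.write(f"# set {curve.set_name}; T={p.temperature_celsius} C; "
                 f"probe={p.probe_conc_molar} M; target={p.target_conc_molar} M; "
                 f"Na={p.monovalent_molar} M; Mg={p.magnesium_molar} M\n")
        fh.write("# concentrations in units of 1e-17 M\n")
        df.to_csv(fh, sep="\t", index=False)


def write_report(path, config: RunConfig | None = None) -> dict:
    """Fixture-based evaluation report: probe counts, concordance,
    classification tallies and the mismatch-position table."""
    from . import hse

    n_sets, n_probes = hse.count_probes()
    conc = hse.concordance_summary()
    t2 = hse.load_table2()
    calls = t2["success_pct"].map(hse.classify).value_counts().to_dict()
    mp = hse.mismatch_position_summary()
    summary = {
        "n_probe_sets": n_sets,
        "n_probes": n_probes,
        **conc,
        "classification_counts": calls,
        "n_pairs": len(mp),
        "n_pairs_improved_gt10": int(mp["improved"].sum()),
        "n_pairs_worsened_gt10": int(mp["worsened"].sum()),
    }
    with open(path, "w") as fh:
        for key, val in summary.items():
            fh.write(f"{key}\t{val}\n")
        fh.write("\n")
        mp.to_csv(fh, sep="\t", index=False)
    if config is not None:
        logger.info("report written with config %s", dataclasses.asdict(config))
    return summary
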