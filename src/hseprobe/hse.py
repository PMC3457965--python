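"""Experimental-table fixtures and the enrichment / concordance analyses.

The packaged TSV fixtures transcribe the published probe table (41 probe
sets, 137 probes), the per-set summary (best tested vs best simulated
length, ddG_M-MM, concordance call) and the two worked per-length series.
On top of them this module computes STR-signal enrichment, its three-way
classification, the headline concordance count, and the effect of moving
the discriminating base from the 3' terminus to the penultimate position.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CORE_PROBE_SETS",
    "catalog_probe_series",
    "HseRecord",
    "PeakPair",
    "load_table1",
    "load_table2",
    "load_table3",
    "parse_length_token",
    "enrichment",
    "classify",
    "concordance_summary",
    "count_probes",
    "mismatch_position_summary",
]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("hseprobe.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def load_table1() -> pd.DataFrame:
    """Probe catalogue: set_name, printed mismatch, sequence, tested_lengths."""
    df = _read_fixture("table1_probes.tsv")
    df["lengths"] = df["tested_lengths"].map(parse_length_token)
    return df


def load_table2() -> pd.DataFrame:
    """Per-set summary with enrichment, ddG, best lengths and concordance call."""
    df = _read_fixture("table2_summary.tsv")
    df["mean_gc_pct"] = df["mean_gc_pct"].astype(float)
    df["ddg_m_mm"] = df["ddg_m_mm"].astype(float)
    df["success_pct"] = df["success_pct"].astype(float)
    df["best_tested"] = df["best_tested_length"].map(_parse_best_lengths)
    df["best_starred"] = df["best_tested_length"].map(
        lambda s: [int(t.rstrip("*")) for t in re.split(r",\s*", s) if t.endswith("*")]
    )
    df["sim_best"] = df["sim_best_length"].map(_parse_best_lengths)
    return df


def load_table3() -> pd.DataFrame:
    """Per-length worked series (P224FC, P30RC) with printed simulation values."""
    df = _read_fixture("table3_series.tsv")
    for col in ("length", "gc_pct", "tm_c", "n"):
        df[col] = pd.to_numeric(df[col])
    for col in ("dg_kcal", "hse_pct", "hse_sd", "con_m_1e17", "con_mm_1e17",
                "delta_con_1e17"):
        df[col] = pd.to_numeric(df[col])
    return df


def parse_length_token(token: str) -> list[int]:
    """Expand a printed tested-length token: "17, 19-22" -> [17, 19, 20, 21, 22]."""
    lengths: list[int] = []
    for part in re.split(r",\s*", str(token).strip()):
        part = part.strip()
        m = re.fullmatch(r"(\d+)\s*[-–]\s*(\d+)", part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise ValueError(f"malformed length range {part!r}")
            lengths.extend(range(lo, hi + 1))
        elif re.fullmatch(r"\d+", part):
            lengths.append(int(part))
        else:
            raise ValueError(f"malformed length token {part!r}")
    return sorted(set(lengths))


def _parse_best_lengths(token: str) -> list[int]:
    token = str(token).strip()
    if token in ("n.s.", "no", "", "nan"):
        return []
    return [int(t.strip().rstrip("*")) for t in re.split(r",\s*", token)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HseRecord:
    """One probe set's experimental outcome and simulation comparison."""

    set_name: str
    best_tested_lengths: list[int]
    success_pct: float
    ddg_m_mm: float
    simulated_best_lengths: list[int]
    concordance_label: str  # "r" | "w" | "n.s."

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_pct <= 100.0:
            raise ValueError("enrichment outside [0, 100]")
        if self.concordance_label not in ("r", "w", "n.s."):
            raise ValueError(f"unknown concordance label {self.concordance_label!r}")


@dataclass(frozen=True)
class PeakPair:
    """STR peak signal for the two contributors at one marker."""

    allele_1_signal: float
    allele_2_signal: float

    def __post_init__(self) -> None:
        if self.allele_1_signal < 0 or self.allele_2_signal < 0:
            raise ValueError("peak signals must be non-negative")
        if self.allele_1_signal == 0 and self.allele_2_signal == 0:
            raise ValueError("both peak signals are zero")


def records_from_table2(df: pd.DataFrame | None = None) -> list[HseRecord]:
    df = df if df is not None else load_table2()
    return [
        HseRecord(r.set_name, list(r.best_tested), r.success_pct, r.ddg_m_mm,
                  list(r.sim_best), r.concordance)
        for r in df.itertuples()
    ]


#: Six designs spanning the catalogue's G/C range (about 25-75% mean G/C),
#: used to study how composition shifts the delta-con optimum.
CORE_PROBE_SETS = ("P30RC", "P224FT", "P224FC", "P224RG", "P244RC", "P38FA")

_NAME_RE = re.compile(r"^(?P<locus>.*)(?P<ori>[FR])(?P<base>[ACGT])(?P<pen>-1)?$")


def catalog_probe_series(set_name: str, min_length: int = 8):
    """Rebuild a catalogued probe set as a simulate-able 5'-trim series.

    Returns ``(probes, mismatch_target_base)``: the length series from
    ``min_length`` up to the full catalogued sequence, and the template base
    of the printed mismatch (second letter of the probe-target pair), ready
    for :func:`hseprobe.probes.delta_con_curve`.
    """
    from .probes import ProbeSpec  # local import to keep layering one-way

    t1 = load_table1()
    row = t1[t1.set_name == set_name]
    if row.empty:
        raise KeyError(f"unknown probe set {set_name!r}")
    full = row["sequence"].item()
    mm_probe, mm_target = row["mismatch"].item().split("-")
    m = _NAME_RE.match(set_name)
    if not m:
        raise ValueError(f"unparseable set name {set_name!r}")
    orientation = "forward" if m.group("ori") == "F" else "reverse"
    offset = 1 if m.group("pen") else 0
    allele = full[len(full) - 1 - offset]
    probes = [
        ProbeSpec(set_name, full[-L:], orientation, offset, allele,
                  mismatch_pair=(mm_probe, mm_target))
        for L in range(min_length, len(full) + 1)
    ]
    return probes, mm_target


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def enrichment(peaks: PeakPair) -> float:
    """Share of total STR signal carried by the dominant contributor, in percent.

    50% means an unseparated mixture, 100% complete separation.  Symmetric in
    contributor labelling.  (The published efficiency equation is rendered
    only as a figure; this symmetric larger-allele share is the documented
    surrogate and reproduces the printed percentages' behaviour.)
    """
    total = peaks.allele_1_signal + peaks.allele_2_signal
    share = max(peaks.allele_1_signal, peaks.allele_2_signal) / total
    return min(100.0 * share, 100.0)


def classify(enrichment_pct: float) -> str:
    """Three-way separation call: >89 complete, 61-89 significant, <=60 none."""
    x = float(enrichment_pct)
    if math.isnan(x) or not 0.0 <= x <= 100.0:
        raise ValueError("enrichment must lie in [0, 100]")
    if x > 89.0:
        return "complete"
    if x >= 61.0:
        return "significant"
    return "none"


def concordance_summary(
    records: list[HseRecord] | None = None,
    rule_window_nt: int = 1,
) -> dict:
    """Concordance between the delta-con prediction and the experimental optimum.

    Counts the printed r/w labels, and separately recomputes a rule-based
    concordance (closest simulated vs best tested length within
    ``rule_window_nt``); the two counts are reported side by side because the
    published labelling is broader than any fixed-window rule.
    """
    records = records if records is not None else records_from_table2()
    if not records:
        raise ValueError("no records")
    missing = [r.set_name for r in records if not r.concordance_label]
    if missing:
        raise ValueError(f"records without concordance labels: {missing}")
    n = len(records)
    n_r = sum(1 for r in records if r.concordance_label == "r")
    n_w = sum(1 for r in records if r.concordance_label == "w")

    rule_hits = 0
    rule_eligible = 0
    for r in records:
        if not r.best_tested_lengths or not r.simulated_best_lengths:
            continue
        rule_eligible += 1
        gap = min(abs(b - s) for b in r.best_tested_lengths
                  for s in r.simulated_best_lengths)
        if gap <= rule_window_nt:
            rule_hits += 1
    return {
        "n_sets": n,
        "n_concordant": n_r,
        "n_discordant": n_w,
        "pct_concordant": 100.0 * n_r / n,
        "rule_window_nt": rule_window_nt,
        "rule_eligible": rule_eligible,
        "rule_concordant": rule_hits,
    }


def count_probes(table1: pd.DataFrame | None = None) -> tuple[int, int]:
    """(number of probe sets, number of distinct probes) in the catalogue."""
    df = table1 if table1 is not None else load_table1()
    n_sets = df["set_name"].nunique()
    n_probes = sum(len(set(lengths)) for lengths in df["lengths"])
    return n_sets, n_probes


def mismatch_position_summary(
    table2: pd.DataFrame | None = None,
    improvement_threshold: float = 10.0,
) -> pd.DataFrame:
    """Enrichment change when the discriminator moves to the penultimate position.

    Pairs every set with its "-1" variant and tabulates best-enrichment
    deltas (penultimate minus terminal); ``improved`` flags gains strictly
    above the threshold, ``worsened`` losses strictly below its negative.
    """
    df = table2 if table2 is not None else load_table2()
    by_name = dict(zip(df["set_name"], df["success_pct"]))
    rows = []
    for name in df["set_name"]:
        if name.endswith("-1"):
            base = name[:-2]
            if base not in by_name:
                raise ValueError(f"unpaired penultimate set {name}")
            delta = by_name[name] - by_name[base]
            rows.append({
                "set_name": base,
                "terminal_pct": by_name[base],
                "penultimate_pct": by_name[name],
                "delta_pct": delta,
                "improved": delta > improvement_threshold,
                "worsened": delta < -improvement_threshold,
            })
    return pd.DataFrame(rows)
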