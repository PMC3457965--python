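"""Synthetic extraction-locus generator.

Stands in for real chromosome flanking sequence: a random background of
configurable G/C composition with a biallelic SNP placed centrally and,
optionally, planted near-copies of the probe binding site at recorded
offsets (with a chosen number of internal mismatches and an intact or
broken 3' end) so the specificity screen has known ground truth.
Regeneration from the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thermo import _clean, complement

__all__ = ["PlantedCopy", "SyntheticLocus", "generate_locus"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedCopy:
    """Ground-truth record of one planted off-target site."""

    position: int
    mismatch_count: int
    three_prime_intact: bool


@dataclass(frozen=True)
class SyntheticLocus:
    sequence: str
    snp_pos: int
    ref_allele: str
    alt_allele: str
    planted: tuple[PlantedCopy, ...]
    seed: int

    def with_allele(self, allele: str) -> str:
        """The locus sequence carrying the given SNP allele."""
        a = allele.upper()
        if a not in (self.ref_allele, self.alt_allele):
            raise ValueError(f"allele {a!r} is neither ref nor alt")
        s = self.sequence
        return s[: self.snp_pos] + a + s[self.snp_pos + 1 :]


def generate_locus(
    seed: int,
    length: int = 5000,
    gc_target: float = 0.40,
    n_offtargets: int = 0,
    ref_allele: str = "C",
    alt_allele: str = "T",
    copy_len: int = 20,
    copy_mismatches: int = 2,
    copy_three_prime_intact: bool = True,
    copy_three_prime_spare: int = 3,
) -> SyntheticLocus:
    """Generate a locus with central SNP and optional planted probe-site copies.

    Planted copies duplicate the ``copy_len`` window ending at the SNP (the
    footprint of a 3'-anchored probe), mutate ``copy_mismatches`` internal
    positions, and optionally break the copy's 3'-terminal base.  Copies are
    placed non-overlapping, away from the design site.
    """
    if length < 2 * copy_len + 10:
        raise ValueError("locus too short for the requested probe footprint")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be in (0, 1)")
    ref = _clean(ref_allele, "ref allele")
    alt = _clean(alt_allele, "alt allele")
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
                  (1 - gc_target) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    snp_pos = length // 2
    arr[snp_pos] = ord(ref)

    design_start = snp_pos - copy_len + 1
    site = arr[design_start : snp_pos + 1].copy()

    planted: list[PlantedCopy] = []
    occupied = [(design_start, snp_pos + 1)]
    attempts = 0
    while len(planted) < n_offtargets:
        attempts += 1
        if attempts > 1000 * max(1, n_offtargets):
            raise ValueError("infeasible planting: could not place non-overlapping copies")
        pos = int(rng.integers(0, length - copy_len))
        if any(pos < e and pos + copy_len > s for s, e in occupied):
            continue
        copy = site.copy()
        if copy_mismatches:
            # internal positions only: spare the first base and, for 3'-intact
            # copies, the whole 3' anchor region
            hi = copy_len - (copy_three_prime_spare if copy_three_prime_intact else 1)
            idx = rng.choice(np.arange(1, hi), size=copy_mismatches,
                             replace=False)
            for i in idx:
                choices = _BASES[_BASES != copy[i]]
                copy[i] = rng.choice(choices)
        if not copy_three_prime_intact:
            choices = _BASES[_BASES != copy[-1]]
            copy[-1] = rng.choice(choices)
        arr[pos : pos + copy_len] = copy
        occupied.append((pos, pos + copy_len))
        planted.append(PlantedCopy(pos, int(copy_mismatches),
                                   bool(copy_three_prime_intact)))

    return SyntheticLocus(arr.tobytes().decode(), snp_pos, ref, alt,
                          tuple(sorted(planted, key=lambda c: c.position)), seed)
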