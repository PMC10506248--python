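"""Adipose sub-depot derivation by mask set arithmetic.

VAT splits into intraperitoneal (IPAT) and retroperitoneal (RPAT) fat, and
SAT splits into deep (DSAT) and superficial (SSAT) fat, by intersecting the
whole-depot mask with a raw outer-contour delineation of one sub-depot and
subtracting. The raw contour may cover non-adipose pixels, so it is clipped
to the parent depot first; the two derived masks therefore always partition
the parent exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .types import BinaryMask


@dataclass
class DepotSet:
    """Co-registered whole-depot masks plus raw sub-depot delineations."""

    vat: BinaryMask
    sat: BinaryMask
    rpat_raw: BinaryMask
    dsat_raw: BinaryMask

    def __post_init__(self):
        shapes = {m.shape for m in (self.vat, self.sat, self.rpat_raw, self.dsat_raw)}
        if len(shapes) != 1:
            raise ValueError(f"all depot masks must share one shape, got {shapes}")


def _split(parent: BinaryMask, raw: BinaryMask, in_label: str,
           out_label: str) -> Tuple[BinaryMask, BinaryMask]:
    if parent.shape != raw.shape:
        raise ValueError(f"shape mismatch: {parent.shape} vs {raw.shape}")
    inner = parent.pixels & raw.pixels
    outer = parent.pixels & ~inner
    return BinaryMask(inner, label=in_label), BinaryMask(outer, label=out_label)


def derive_ipat(vat: BinaryMask, rpat_raw: BinaryMask) -> Tuple[BinaryMask, BinaryMask]:
    """Return ``(rpat, ipat)``: RPAT = VAT ∩ raw, IPAT = VAT \\ RPAT."""
    return _split(vat, rpat_raw, "rpat", "ipat")


def derive_dsat_ssat(sat: BinaryMask, dsat_raw: BinaryMask) -> Tuple[BinaryMask, BinaryMask]:
    """Return ``(dsat, ssat)``: DSAT = SAT ∩ raw, SSAT = SAT \\ DSAT."""
    return _split(sat, dsat_raw, "dsat", "ssat")


def derive_all(depots: DepotSet) -> dict:
    """Derive the four sub-depots from a full :class:`DepotSet`."""
    rpat, ipat = derive_ipat(depots.vat, depots.rpat_raw)
    dsat, ssat = derive_dsat_ssat(depots.sat, depots.dsat_raw)
    return {"rpat": rpat, "ipat": ipat, "dsat": dsat, "ssat": ssat}
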