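"""Carbon-molar (Cmmol) conversion and carbon-uptake partitioning.

Substrates with different carbon content are compared on a carbon-mole
basis: a specific rate in mmol/gDW/h times the molecule's carbon count
gives Cmmol/gDW/h. The share of each co-consumed substrate in total carbon
uptake is its Cmmol rate over the Cmmol sum. Rates here are
uptake-positive — conversion from the model's production-positive sign
happens at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError

__all__ = ["SubstrateCarbon", "DEFAULT_CARBON_COUNTS", "to_cmmol", "carbon_shares", "carbon_table"]

#: Carbon atoms per molecule for the study's substrates.
DEFAULT_CARBON_COUNTS = {"DHA": 3, "formate": 1, "glycolate": 2, "acetate": 2}


@dataclass(frozen=True)
class SubstrateCarbon:
    """A substrate's carbon count and uptake-positive specific rate."""

    name: str
    carbon_count: int
    rate: float  # mmol/gDW/h, uptake positive

    def __post_init__(self) -> None:
        if self.carbon_count < 1 or int(self.carbon_count) != self.carbon_count:
            raise InputError(f"{self.name}: carbon count must be a positive integer")
        if self.rate < 0:
            raise InputError(f"{self.name}: uptake rate must be >= 0, got {self.rate}")


def to_cmmol(rate: float, carbon_count: int) -> float:
    """Convert mmol/gDW/h to Cmmol/gDW/h: rate * carbon_count."""
    if rate < 0:
        raise InputError(f"rate must be >= 0, got {rate}")
    if carbon_count < 1:
        raise InputError(f"carbon count must be >= 1, got {carbon_count}")
    return rate * carbon_count


def carbon_shares(substrates: list[SubstrateCarbon]) -> dict[str, float]:
    """Fraction of total carbon uptake carried by each substrate.

    share_i = rate_i * C_i / sum_j rate_j * C_j; the shares sum to 1.
    """
    if not substrates:
        raise InputError("need at least one substrate")
    cmmol = {s.name: to_cmmol(s.rate, s.carbon_count) for s in substrates}
    total = sum(cmmol.values())
    if total <= 0:
        raise InputError("all rates are zero; shares undefined")
    return {name: v / total for name, v in cmmol.items()}


def carbon_table(substrates: list[SubstrateCarbon]) -> pd.DataFrame:
    """Tabular report: name, rate (mmol), rate (Cmmol), share of carbon uptake."""
    shares = carbon_shares(substrates)
    return pd.DataFrame(
        {
            "name": [s.name for s in substrates],
            "rate_mmol": [s.rate for s in substrates],
            "rate_cmmol": [to_cmmol(s.rate, s.carbon_count) for s in substrates],
            "share": [shares[s.name] for s in substrates],
        }
    )
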