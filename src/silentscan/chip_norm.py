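"""ChIP-qPCR quantification: percent-of-input and reference normalization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_INPUT_FRACTION = 0.10
DEFAULT_EFFICIENCY = 2.0


@dataclass(frozen=True)
class QpcrMeasurement:
    region: str
    mark: str
    strain: str
    cq_ip: float
    cq_input: float
    input_fraction: float = DEFAULT_INPUT_FRACTION
    efficiency: float = DEFAULT_EFFICIENCY
    replicate: int = 1

    def __post_init__(self):
        if self.cq_ip <= 0 or self.cq_input <= 0:
            raise ValueError("Cq values must be positive")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")
        if not (1 < self.efficiency <= 2):
            raise ValueError("efficiency must be in (1, 2]")


def percent_input(m: QpcrMeasurement) -> float:
    """percent = 100 * input_fraction * efficiency ** (Cq_input - Cq_IP)."""
    return 100.0 * m.input_fraction * m.efficiency ** (m.cq_input - m.cq_ip)


def normalize_to_reference(percent_by_region: Mapping[str, float], reference_region: str) -> dict:
    """Divide each region's percent-input by the reference region's value."""
    if reference_region not in percent_by_region:
        raise KeyError(f"reference region {reference_region!r} missing")
    ref = percent_by_region[reference_region]
    if ref <= 0:
        raise ValueError("reference signal must be positive")
    return {region: value / ref for region, value in percent_by_region.items()}


def enrichment_table(
    cq_table: pd.DataFrame,
    reference_region: str,
    input_fraction: float = DEFAULT_INPUT_FRACTION,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Replicate-wise percent-input and reference normalization, then mean,
    SD and SE over replicates.

    Expects columns strain, mark, region, replicate, cq_ip, cq_input.
    Normalization happens within each (strain, mark, replicate) block, so the
    reference region maps to exactly 1 in every replicate.
    """
    required = {"strain", "mark", "region", "replicate", "cq_ip", "cq_input"}
    missing = required - set(cq_table.columns)
    if missing:
        raise ValueError(f"Cq table missing columns {sorted(missing)}")

    rows = []
    for (strain, mark, rep), block in cq_table.groupby(["strain", "mark", "replicate"]):
        percents = {}
        for _, r in block.iterrows():
            m = QpcrMeasurement(
                region=r["region"], mark=mark, strain=strain,
                cq_ip=float(r["cq_ip"]), cq_input=float(r["cq_input"]),
                input_fraction=input_fraction, efficiency=efficiency,
                replicate=int(rep),
            )
            percents[r["region"]] = percent_input(m)
        normalized = normalize_to_reference(percents, reference_region)
        for region in percents:
            rows.append(
                {
                    "strain": strain, "mark": mark, "region": region,
                    "replicate": int(rep),
                    "percent_input": percents[region],
                    "normalized": normalized[region],
                }
            )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby(["strain", "mark", "region"])
        .agg(
            percent_input=("percent_input", "mean"),
            normalized=("normalized", "mean"),
            normalized_sd=("normalized", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
            n_replicates=("replicate", "count"),
        )
        .reset_index()
    )
    agg["normalized_se"] = agg["normalized_sd"] / np.sqrt(agg["n_replicates"])
    return agg
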