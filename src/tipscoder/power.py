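"""Clinical-current-unit arithmetic and the net power-savings model.

Removing pulses saves stimulation power, but restoring comfortable
loudness afterwards requires raising the global current level, which
costs some of it back. The model assumes the radio-frequency coil link
accounts for a fixed fraction of total device power (default 90%) and
that this component scales linearly with stimulation level, so

    saving(%) = 100 * coil_fraction * (1 - f_kept * (1 + delta_q))

where f_kept is the fraction of pulses retained and delta_q the
fractional charge increase of the global comfortable level. Charge steps
are expressed in clinical current units, a logarithmic ladder with 0.157
dB per CU.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


# The device current ladder is exactly logarithmic with 40/255 dB per
# clinical current unit; 0.157 dB is the conventional rounded value.
CU_STEP_DB_EXACT = 40.0 / 255.0


@dataclass(frozen=True)
class PowerModelConfig:
    coil_fraction: float = 0.9
    cu_step_db: float = 0.157

    def __post_init__(self):
        if not 0.0 < self.coil_fraction <= 1.0:
            raise ValueError("coil_fraction must be in (0, 1]")
        if self.cu_step_db <= 0:
            raise ValueError("cu_step_db must be positive")


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (report parity)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cu_ratio(n_cu: float, cfg: PowerModelConfig | None = None) -> float:
    """Linear charge ratio of an ``n_cu``-step change: 10^(n*0.157/20)."""
    cfg = cfg or PowerModelConfig()
    return float(10.0 ** (n_cu * cfg.cu_step_db / 20.0))


def cu_percent_change(n_cu: float, cfg: PowerModelConfig | None = None) -> float:
    """Percentage charge change of an ``n_cu``-step change, 2 decimals."""
    return round2(100.0 * (cu_ratio(n_cu, cfg) - 1.0))


def net_power_saving(
    fraction_kept: float,
    delta_q: float,
    cfg: PowerModelConfig | None = None,
    rounded: bool = True,
) -> float:
    """Net power saving (%) after pruning and loudness restoration.

    ``fraction_kept`` in (0, 1]; ``delta_q`` is the fractional charge
    change (0.0557 for +5.57%). Strictly decreasing in both arguments.
    """
    cfg = cfg or PowerModelConfig()
    if not 0.0 < fraction_kept <= 1.0:
        raise ValueError("fraction_kept must be in (0, 1]")
    if 1.0 + delta_q <= 0.0:
        raise ValueError("1 + delta_q must be positive")
    saving = 100.0 * cfg.coil_fraction * (1.0 - fraction_kept * (1.0 + delta_q))
    return round2(saving) if rounded else saving


# Fractions of pulses retained in the three sparsification conditions:
# removing half, exactly one third, and half of the pulses respectively.
CONDITION_KEPT = {
    "tips50_cis": 0.5,
    "tips33_ace": 2.0 / 3.0,
    "tips50_ace": 0.5,
}


def table2_report(
    charge_percent_columns: dict,
    cfg: PowerModelConfig | None = None,
) -> pd.DataFrame:
    """Per-participant savings and column averages from printed charge
    increases (%).

    ``charge_percent_columns`` maps a condition name in ``CONDITION_KEPT``
    to a sequence of per-participant charge percentages; entries may be
    None/NaN/"-" for participants missing from a condition. Returns a
    DataFrame of savings with an "Avg" row over available entries.

    The "Avg" row follows the published-table convention: the charge
    column is averaged and rounded to 2 decimals first, and the model is
    applied to that average with the kept fraction also rounded to 2
    decimals (2/3 enters as 0.67). Per-participant rows use the exact
    kept fraction. The two conventions differ only in the one-third-
    removed condition, where the table they reproduce is itself internally
    inconsistent between its cells and its average row.
    """
    cfg = cfg or PowerModelConfig()
    out = {}
    for cond, column in charge_percent_columns.items():
        if cond not in CONDITION_KEPT:
            raise KeyError(
                f"unknown condition {cond!r}; expected one of {sorted(CONDITION_KEPT)}"
            )
        kept = CONDITION_KEPT[cond]
        savings, charges = [], []
        for entry in column:
            if entry is None or (
                isinstance(entry, str) and entry.strip() in ("-", "–", "—", "")
            ):
                savings.append(np.nan)
                continue
            try:
                pct = float(entry)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric charge entry {entry!r} in {cond}")
            if not np.isfinite(pct):
                savings.append(np.nan)
                continue
            charges.append(pct)
            savings.append(net_power_saving(kept, pct / 100.0, cfg))
        col = pd.Series(savings, dtype=float)
        avg_charge = round2(float(np.mean(charges)))
        avg = net_power_saving(round(kept, 2), avg_charge / 100.0, cfg)
        out[cond] = pd.concat([col, pd.Series([avg], index=["Avg"])])
    return pd.DataFrame(out)
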