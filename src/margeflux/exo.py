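"""Exchange-flux constraints from spent-medium metabolomics.

Extracellular abundances measured in two experimental conditions are
compared against the pure-medium baseline.  A significant drop below the
baseline is read as uptake, a significant rise as secretion.  Each call
yields (i) a direction on the exchange flux, (ii) an absolute magnitude
floor — a small fraction of the exchange's maximum feasible uptake rate
— guaranteeing minimal activity in the data-supported direction, and
(iii), when the between-condition change is itself significant and both
conditions agree in direction, a relative interval on the ratio of
baseline-subtracted magnitudes, widened by a deviation tolerance to
absorb measurement error.

Because cultivation intervals are equal across conditions (medium
renewed on a fixed schedule), endpoint-concentration differences stand
in for average rates; significance testing itself happens upstream and
arrives here as boolean flags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import ExtendedModel, max_uptake_rate

logger = logging.getLogger(__name__)

UPTAKE = "uptake"
SECRETION = "secretion"
UNCONSTRAINED = "unconstrained"

#: Default relative deviation tolerance on between-condition fold changes.
DEFAULT_TAU = 0.5
#: Default activation fraction: floors are this fraction of max uptake.
DEFAULT_PHI = 0.01


@dataclass
class ExoMeasurement:
    """One extracellular metabolite in two conditions plus the pure medium."""

    metabolite_id: str
    exchange_id: str
    abundance_a: float
    abundance_b: float
    abundance_media: float
    sig_vs_media_a: bool
    sig_vs_media_b: bool
    sig_between: bool

    def __post_init__(self) -> None:
        for label in ("abundance_a", "abundance_b", "abundance_media"):
            v = getattr(self, label)
            if not (v >= 0 and v == v and abs(v) != float("inf")):
                raise ValueError(f"{self.metabolite_id}: {label} must be finite and >= 0, got {v}")


@dataclass
class ExchangeConstraint:
    """Derived constraints for one exchange reaction."""

    exchange_id: str
    metabolite_id: str
    direction_a: str = UNCONSTRAINED
    direction_b: str = UNCONSTRAINED
    abs_floor_a: float = 0.0
    abs_floor_b: float = 0.0
    ratio_interval: tuple[float, float] | None = None  # on magnitude_b / magnitude_a


@dataclass
class ExchangeConstraintSet:
    constraints: dict[str, ExchangeConstraint] = field(default_factory=dict)
    tau: float = DEFAULT_TAU
    phi: float = DEFAULT_PHI
    log: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.constraints.values())

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "phi": self.phi,
            "constraints": {
                ex: {
                    "metabolite_id": c.metabolite_id,
                    "direction_a": c.direction_a,
                    "direction_b": c.direction_b,
                    "abs_floor_a": c.abs_floor_a,
                    "abs_floor_b": c.abs_floor_b,
                    "ratio_interval": list(c.ratio_interval) if c.ratio_interval else None,
                }
                for ex, c in self.constraints.items()
            },
            "log": list(self.log),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def call_direction(m: ExoMeasurement, condition: str) -> str:
    """Uptake / secretion / unconstrained call for one condition.

    Secretion if the abundance rose significantly above the pure-medium
    baseline, uptake if it fell significantly below, otherwise no call.
    """
    if condition == "a":
        abundance, sig = m.abundance_a, m.sig_vs_media_a
    elif condition == "b":
        abundance, sig = m.abundance_b, m.sig_vs_media_b
    else:
        raise ValueError(f"condition must be 'a' or 'b', got {condition!r}")
    if not sig:
        return UNCONSTRAINED
    if abundance > m.abundance_media:
        return SECRETION
    if abundance < m.abundance_media:
        return UPTAKE
    return UNCONSTRAINED


def build_constraints(
    measurements: list[ExoMeasurement],
    ext: ExtendedModel,
    tau: float = DEFAULT_TAU,
    phi: float = DEFAULT_PHI,
) -> ExchangeConstraintSet:
    """Derive the full exchange constraint set from measurements.

    Floors are ``phi * max_uptake_rate(exchange)`` wherever a direction
    was called.  Ratio intervals ``[FC*(1-tau), FC*(1+tau)]`` with
    ``FC = |abundance_b - media| / |abundance_a - media|`` are attached
    only when the between-condition change is significant, both
    conditions carry the same direction call, and the denominator delta
    is nonzero; opposite-direction pairs keep their floors but no ratio
    (a signed magnitude ratio has no linear encoding).
    """
    out = ExchangeConstraintSet(tau=tau, phi=phi)
    for m in measurements:
        if m.exchange_id not in ext.base.exchange_ids:
            msg = f"{m.metabolite_id}: no exchange reaction {m.exchange_id!r} in model; skipped"
            logger.warning(msg)
            out.log.append(msg)
            continue
        con = ExchangeConstraint(m.exchange_id, m.metabolite_id)
        con.direction_a = call_direction(m, "a")
        con.direction_b = call_direction(m, "b")
        if con.direction_a != UNCONSTRAINED or con.direction_b != UNCONSTRAINED:
            vmax = max_uptake_rate(ext, m.exchange_id)
            if con.direction_a != UNCONSTRAINED:
                con.abs_floor_a = phi * vmax
            if con.direction_b != UNCONSTRAINED:
                con.abs_floor_b = phi * vmax
        if m.sig_between:
            if (
                con.direction_a == UNCONSTRAINED
                or con.direction_b == UNCONSTRAINED
            ):
                out.log.append(
                    f"{m.metabolite_id}: between-condition change significant but a "
                    "direction call is missing; no ratio constraint"
                )
            elif con.direction_a != con.direction_b:
                msg = (
                    f"{m.metabolite_id}: opposite direction calls "
                    f"({con.direction_a} vs {con.direction_b}); ratio constraint skipped"
                )
                logger.info(msg)
                out.log.append(msg)
            else:
                delta_a = abs(m.abundance_a - m.abundance_media)
                delta_b = abs(m.abundance_b - m.abundance_media)
                if delta_a == 0:
                    msg = f"{m.metabolite_id}: zero baseline-subtracted delta in condition a; no ratio constraint"
                    logger.warning(msg)
                    out.log.append(msg)
                else:
                    fc = delta_b / delta_a
                    low = max(0.0, fc * (1.0 - tau))
                    high = fc * (1.0 + tau)
                    con.ratio_interval = (low, high)
        out.constraints[m.exchange_id] = con
    return out


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

_COLUMNS = [
    "metabolite_id",
    "exchange_id",
    "abundance_a",
    "abundance_b",
    "abundance_media",
    "sig_vs_media_a",
    "sig_vs_media_b",
    "sig_between",
]


def read_exomet_tsv(path) -> list[ExoMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"exometabolome table {path}: missing columns {sorted(missing)}")
    return measurements_from_frame(df)


def measurements_from_frame(df: pd.DataFrame) -> list[ExoMeasurement]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExoMeasurement(
                metabolite_id=str(row.metabolite_id),
                exchange_id=str(row.exchange_id),
                abundance_a=float(row.abundance_a),
                abundance_b=float(row.abundance_b),
                abundance_media=float(row.abundance_media),
                sig_vs_media_a=_to_bool(row.sig_vs_media_a),
                sig_vs_media_b=_to_bool(row.sig_vs_media_b),
                sig_between=_to_bool(row.sig_between),
            )
        )
    return out


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)
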