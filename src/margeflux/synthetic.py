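"""Deterministic toy network and seeded two-condition data generators.

The toy model is a nine-metabolite, thirteen-reaction network with the
qualitative anatomy the two-condition method needs: glucose uptake and
transport, a lumped glycolysis (with an isozyme pair at the hexokinase
step and a two-subunit complex downstream), a fermentative branch
(reversible lactate dehydrogenase with two isozymes, lactate export)
competing with an oxidative branch for pyruvate, glutamine uptake and
catabolism, a biomass drain and an energy sink.  Condition *b* plants a
fold change on the fermentative and oxidative branches relative to
condition *a* (default: fermentation doubled, oxidation at 0.8x — the
tumor-like template of elevated glycolytic fermentation), and the
ground-truth flux pair is constructed to balance exactly, so every
planted shift is realizable by a feasible solution.

The generators emit the same table shapes the pipeline consumes from
real data: per-gene log2 fold changes with q-values (q-values are
synthesized rank-based, since differential-expression testing is
upstream of this package), and extracellular abundances per condition
plus the pure-medium baseline with significance flags derived from the
noise model.  One time unit elapses between medium change and sampling,
so concentration deltas equal average exchange fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction
from .gpr import parse_gpr

#: Versioned manifest of the toy network; tests check the built model
#: against these counts.
TOY_MANIFEST = {
    "n_metabolites": 9,
    "n_reactions": 13,
    "n_gpr_reactions": 7,
    "n_exchanges": 3,
    "n_usage_columns": 11,
}

#: reaction -> pathway labels for flux-share summaries
DEFAULT_PATHWAY_MAP = {
    "HEX": "glycolysis",
    "GLYC": "glycolysis",
    "LDH": "fermentative",
    "LACT": "fermentative",
    "OXPHOS": "oxidative",
    "GLNT": "glutaminolysis",
    "GLS": "glutaminolysis",
}

#: the two competing pyruvate branches, used for planted-shift recovery
BRANCH_MAP = {"LDH": "fermentative", "OXPHOS": "oxidative"}


def make_toy_model() -> MetabolicModel:
    """Fixed, versioned toy network; identical output on every call."""
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("lac_e", "lactate", "e"),
        Metabolite("gln_e", "glutamine", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("g6p", "glucose-6-phosphate", "c"),
        Metabolite("pyr", "pyruvate", "c"),
        Metabolite("lac_c", "lactate", "c"),
        Metabolite("gln_c", "glutamine", "c"),
        Metabolite("nrg", "energy equivalent", "c"),
    ]
    rxns = [
        Reaction("EX_glc", {"glc_e": -1}, -10.0, 0.0, "glucose exchange"),
        Reaction("GLCT", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0, "glucose transport"),
        Reaction("HEX", {"glc_c": -1, "g6p": 1}, 0.0, 1000.0, "hexokinase"),
        Reaction("GLYC", {"g6p": -1, "pyr": 2, "nrg": 2}, 0.0, 1000.0, "lower glycolysis"),
        Reaction("LDH", {"pyr": -1, "lac_c": 1}, -1000.0, 1000.0, "lactate dehydrogenase"),
        Reaction("LACT", {"lac_c": -1, "lac_e": 1}, -1000.0, 1000.0, "lactate transport"),
        Reaction("EX_lac", {"lac_e": -1}, -10.0, 1000.0, "lactate exchange"),
        Reaction("OXPHOS", {"pyr": -1, "nrg": 15}, 0.0, 1000.0, "oxidative branch"),
        Reaction("GLNT", {"gln_e": -1, "gln_c": 1}, 0.0, 1000.0, "glutamine transport"),
        Reaction("EX_gln", {"gln_e": -1}, -5.0, 0.0, "glutamine exchange"),
        Reaction("GLS", {"gln_c": -1, "nrg": 8}, 0.0, 1000.0, "glutaminolysis"),
        Reaction("BIOMASS", {"g6p": -0.5, "gln_c": -0.5, "nrg": -10}, 0.0, 1000.0, "biomass drain"),
        Reaction("NRG_SINK", {"nrg": -1}, 0.0, 1000.0, "energy dissipation"),
    ]
    gprs = {
        "GLCT": parse_gpr("gGLUT1"),
        "HEX": parse_gpr("gHK1 or gHK2"),
        "GLYC": parse_gpr("gGAPDH and gPGK"),
        "LDH": parse_gpr("gLDHA or gLDHB"),
        "OXPHOS": parse_gpr("gPDH and gDLD"),
        "GLNT": parse_gpr("gSLC1A5"),
        "GLS": parse_gpr("gGLS"),
    }
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        gpr_rules=gprs,
        exchange_ids={"EX_glc", "EX_lac", "EX_gln"},
        biomass_id="BIOMASS",
    )


@dataclass
class ToyScenario:
    """Planted two-condition shift on the toy network.

    fermentative_fold / oxidative_fold
        Flux fold change of condition b over a on the LDH and OXPHOS
        branches; defaults plant a doubled fermentative flux against a
        mildly reduced oxidative flux.
    expression_sigma
        Gaussian noise (log2 units) added to the planted gene fold
        changes.
    abundance_sigma
        Multiplicative log-normal noise on extracellular abundances.
    """

    seed: int = 0
    fermentative_fold: float = 2.0
    oxidative_fold: float = 0.8
    expression_sigma: float = 0.1
    abundance_sigma: float = 0.1
    media: dict = field(
        default_factory=lambda: {"glc": 20.0, "lac": 0.0, "gln": 5.0}
    )


@dataclass
class SimulatedConditionPair:
    expression: pd.DataFrame  # gene_id, log2fc, qvalue
    exomet: pd.DataFrame  # exo_constraints input schema
    truth_flux_a: dict[str, float]
    truth_flux_b: dict[str, float]
    scenario: ToyScenario


def _truth_fluxes(scn: ToyScenario) -> tuple[dict[str, float], dict[str, float]]:
    """Exactly mass-balanced flux pair realizing the planted branch folds."""
    ldh_a, ox_a, gln_up, bio = 4.0, 5.0, 1.0, 1.0

    def build(ldh: float, ox: float) -> dict[str, float]:
        pyr = ldh + ox
        glyc = pyr / 2.0
        hexk = glyc + 0.5 * bio
        nrg = 2.0 * glyc + 15.0 * ox + 8.0 * (gln_up - 0.5 * bio)
        return {
            "EX_glc": -hexk,
            "GLCT": hexk,
            "HEX": hexk,
            "GLYC": glyc,
            "LDH": ldh,
            "LACT": ldh,
            "EX_lac": ldh,
            "OXPHOS": ox,
            "GLNT": gln_up,
            "EX_gln": -gln_up,
            "GLS": gln_up - 0.5 * bio,
            "BIOMASS": bio,
            "NRG_SINK": nrg - 10.0 * bio,
        }

    v_a = build(ldh_a, ox_a)
    v_b = build(ldh_a * scn.fermentative_fold, ox_a * scn.oxidative_fold)
    model = make_toy_model()
    for label, v in (("a", v_a), ("b", v_b)):
        resid = _mass_balance(model, v)
        if resid > 1e-9:
            raise ValueError(f"planted condition {label} not mass balanced (residual {resid})")
        for rid, val in v.items():
            rxn = model.reaction(rid)
            if not (rxn.lb - 1e-9 <= val <= rxn.ub + 1e-9):
                raise ValueError(f"planted flux {rid}={val} violates bounds in condition {label}")
    return v_a, v_b


def _mass_balance(model: MetabolicModel, v: dict[str, float]) -> float:
    S = model.stoichiometric_matrix()
    vec = np.array([v[r] for r in model.reaction_ids])
    return float(np.abs(S @ vec).max())


def simulate_condition_pair(scenario: ToyScenario | None = None) -> SimulatedConditionPair:
    """Generate a seeded expression/exometabolome pair with known truth."""
    scn = scenario or ToyScenario()
    rng = np.random.default_rng(scn.seed)
    model = make_toy_model()
    v_a, v_b = _truth_fluxes(scn)

    # --- expression: each enzyme gene mirrors its reaction's flux ratio ---
    rows = []
    gene_lfc: dict[str, float] = {}
    for rid, rule in model.gpr_rules.items():
        if v_a[rid] <= 0:
            continue
        lfc = float(np.log2(v_b[rid] / v_a[rid]))
        for g in sorted(rule.genes):
            gene_lfc[g] = lfc
    planted = [g for g, l in sorted(gene_lfc.items()) if abs(l) > 1e-9]
    unplanted = [g for g, l in sorted(gene_lfc.items()) if abs(l) <= 1e-9]
    for i, g in enumerate(planted):
        noisy = gene_lfc[g] + rng.normal(0.0, scn.expression_sigma)
        q = 0.05 * (i + 1) / max(1, len(planted))  # below the q<0.1 convention
        rows.append((g, noisy, q))
    for i, g in enumerate(unplanted):
        noisy = gene_lfc[g] + rng.normal(0.0, scn.expression_sigma)
        q = 0.3 + 0.6 * (i + 1) / max(1, len(unplanted))
        rows.append((g, noisy, q))
    expression = pd.DataFrame(rows, columns=["gene_id", "log2fc", "qvalue"])

    # --- exometabolome: unit sampling interval, so deltas equal fluxes ---
    ex_map = {"glc": "EX_glc", "lac": "EX_lac", "gln": "EX_gln"}
    sig = scn.abundance_sigma
    recs = []
    for met, ex in ex_map.items():
        media_true = scn.media[met]
        # positive exchange flux secretes into the medium
        abund_a_true = media_true + v_a[ex]
        abund_b_true = media_true + v_b[ex]
        if min(abund_a_true, abund_b_true) < 0:
            raise ValueError(f"planted fluxes drain {met} below zero abundance")

        def noisy(x: float) -> float:
            if sig <= 0 or x == 0:
                return x
            return float(x * np.exp(rng.normal(0.0, sig)))

        media = noisy(media_true)
        aa = noisy(abund_a_true)
        ab = noisy(abund_b_true)

        def sig_vs_media(abund: float) -> bool:
            if sig <= 0:
                return abs(abund - media) > 0
            return abs(abund - media) > 2.0 * sig * max(media, abund)

        da, db = abs(aa - media), abs(ab - media)
        if sig <= 0:
            sig_between = abs(db - da) > 0
        else:
            sig_between = abs(db - da) > 2.0 * sig * max(media, aa, ab)
        recs.append(
            (met, ex, aa, ab, media, sig_vs_media(aa), sig_vs_media(ab), sig_between)
        )
    exomet = pd.DataFrame(
        recs,
        columns=[
            "metabolite_id",
            "exchange_id",
            "abundance_a",
            "abundance_b",
            "abundance_media",
            "sig_vs_media_a",
            "sig_vs_media_b",
            "sig_between",
        ],
    )
    return SimulatedConditionPair(expression, exomet, v_a, v_b, scn)
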