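"""Reporter-metabolite enrichment.

A metabolite is scored by aggregating the significance of its
neighboring genes — the genes of the reactions that produce or consume
it, taken from the model's GPR rules.  Gene p-values are mapped through
the standard-normal quantile and summed,

    Z = (1/sqrt(k)) * sum_g inverse_Phi(1 - p_g),

so small member p-values push Z up.  A permutation background (random
gene sets of the same size drawn from the tested gene pool) supplies
mean and standard deviation per set size; the corrected Z and its
upper-tail permutation p-value are reported per directional class:

non-directional
    two-sided p-values as given, all genes.
distinct-directional
    one-tailed p (p/2 on the fold-change sign side, 1 - p/2 on the
    other), all genes; positive Z means coordinated upregulation.
mixed-directional up / down
    the up- (down-) regulated members only, with their one-tailed p/2.

Adjusted p-values are Benjamini-Hochberg within each class, and the
significance flag additionally caps the number of reported metabolites
per class at a top fraction of the tested list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .model import MetabolicModel

logger = logging.getLogger(__name__)

CLASSES = ("non_directional", "distinct_directional", "mixed_up", "mixed_down")

#: p-values are clipped to [clip, 1-clip] before the quantile transform.
DEFAULT_CLIP = 1e-10

#: exact per-size background up to this set size; larger sizes share bins
_EXACT_K_MAX = 50
_BIN_WIDTH = 10


class ReporterError(ValueError):
    pass


@dataclass
class GeneStats:
    """Gene-level p-values and fold-change signs."""

    pvalues: dict[str, float]
    signs: dict[str, int]  # +1 / -1 / 0 from log2 fold change
    clip: float = DEFAULT_CLIP

    def __post_init__(self) -> None:
        self.pvalues = {
            g: float(np.clip(p, self.clip, 1.0 - self.clip)) for g, p in self.pvalues.items()
        }

    @classmethod
    def from_frame(cls, df: pd.DataFrame, clip: float = DEFAULT_CLIP) -> "GeneStats":
        required = {"gene_id", "pvalue", "log2fc"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene stats table missing columns {sorted(missing)}")
        pvals = {str(r.gene_id): float(r.pvalue) for r in df.itertuples(index=False)}
        signs = {str(r.gene_id): int(np.sign(r.log2fc)) for r in df.itertuples(index=False)}
        return cls(pvals, signs, clip)

    @classmethod
    def from_tsv(cls, path, clip: float = DEFAULT_CLIP) -> "GeneStats":
        return cls.from_frame(pd.read_csv(path, sep="\t"), clip)


def reporter_z(pvals) -> float:
    """Raw reporter statistic for one gene set."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ReporterError("empty gene set")
    return float(norm.ppf(1.0 - p).sum() / np.sqrt(p.size))


def gene_sets_from_model(model: MetabolicModel) -> dict[str, set[str]]:
    """Metabolite -> genes of the GPR-bearing reactions touching it."""
    sets: dict[str, set[str]] = {}
    for rxn in model.reactions:
        rule = model.gpr_rules.get(rxn.id)
        if rule is None:
            continue
        for met, coef in rxn.stoichiometry.items():
            if coef != 0:
                sets.setdefault(met, set()).update(rule.genes)
    return {m: g for m, g in sets.items() if g}


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set format: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------


def _class_values(stats: GeneStats, cls: str) -> dict[str, float]:
    """Per-gene quantile-transformed value for one directional class."""
    out = {}
    for g, p in stats.pvalues.items():
        sign = stats.signs.get(g, 0)
        if cls == "non_directional":
            q = p
        elif cls == "distinct_directional":
            q = p / 2.0 if sign > 0 else 1.0 - p / 2.0
        elif cls == "mixed_up":
            if sign <= 0:
                continue
            q = p / 2.0
        elif cls == "mixed_down":
            if sign >= 0:
                continue
            q = p / 2.0
        else:  # pragma: no cover
            raise ReporterError(f"unknown class {cls!r}")
        out[g] = float(norm.ppf(1.0 - np.clip(q, stats.clip, 1.0 - stats.clip)))
    return out


def _bin_size(k: int) -> int:
    if k <= _EXACT_K_MAX:
        return k
    return int(round(k / _BIN_WIDTH) * _BIN_WIDTH)


class ReporterAnalysis:
    """Reporter-metabolite model: gene statistics on a metabolic network.

    Parameters
    ----------
    stats : GeneStats or DataFrame (gene_id, pvalue, log2fc columns)
    sets : mapping metabolite -> gene ids, or a MetabolicModel whose GPR
        rules the sets are derived from.  Sets of at least one tested
        gene are retained.
    """

    def __init__(
        self,
        stats: GeneStats | pd.DataFrame,
        sets: dict[str, set[str]] | MetabolicModel,
    ) -> None:
        if isinstance(stats, pd.DataFrame):
            stats = GeneStats.from_frame(stats)
        self.stats = stats
        if isinstance(sets, MetabolicModel):
            sets = gene_sets_from_model(sets)
        self.sets = {m: set(g) for m, g in sets.items()}

    def fit(
        self,
        n_perm: int = 10_000,
        seed: int | None = None,
        adj_p_threshold: float = 0.01,
        top_fraction: float = 0.05,
    ) -> "ReporterResults":
        """Run all four directional classes with a shared permutation seed.

        Permutations draw gene labels without replacement from the
        class's tested gene pool, per set size; significance requires
        both an adjusted p below `adj_p_threshold` and a rank within the
        top `top_fraction` of the tested metabolite list.
        """
        if n_perm < 100:
            raise ReporterError("n_perm must be at least 100")
        rng = np.random.default_rng(seed)
        tables: dict[str, pd.DataFrame] = {}
        dropped: list[str] = []
        for cls in CLASSES:
            values = _class_values(self.stats, cls)
            pool = np.array([values[g] for g in sorted(values)])
            rows = []
            for met in sorted(self.sets):
                members = sorted(g for g in self.sets[met] if g in values)
                if not members:
                    if cls == "non_directional" and not any(
                        g in self.stats.pvalues for g in self.sets[met]
                    ):
                        dropped.append(met)
                    continue
                k = len(members)
                z = float(sum(values[g] for g in members) / np.sqrt(k))
                rows.append((met, k, z, ",".join(members)))
            if not rows:
                tables[cls] = pd.DataFrame(
                    columns=["k", "z_raw", "z_corrected", "pvalue", "padj", "significant", "genes"]
                )
                continue

            # permutation background per (binned) set size
            sizes = sorted({_bin_size(k) for _, k, _, _ in rows})
            background: dict[int, tuple[float, float, np.ndarray]] = {}
            for k in sizes:
                kk = min(k, pool.size)
                draws = np.empty(n_perm)
                for i in range(n_perm):
                    idx = rng.choice(pool.size, size=kk, replace=False)
                    draws[i] = pool[idx].sum() / np.sqrt(kk)
                background[k] = (float(draws.mean()), float(draws.std(ddof=0)), draws)

            recs = []
            for met, k, z, genes in rows:
                mu, sd, draws = background[_bin_size(k)]
                zc = (z - mu) / sd if sd > 0 else 0.0
                pval = (1.0 + float((draws >= z).sum())) / (n_perm + 1.0)
                recs.append((met, k, z, zc, pval, genes))
            df = pd.DataFrame(
                recs, columns=["metabolite", "k", "z_raw", "z_corrected", "pvalue", "genes"]
            ).set_index("metabolite")
            df["padj"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
            n_tested = len(df)
            cap = int(np.floor(top_fraction * n_tested))
            rank = df["padj"].rank(method="first")
            df["significant"] = (df["padj"] < adj_p_threshold) & (rank <= cap)
            tables[cls] = df[["k", "z_raw", "z_corrected", "pvalue", "padj", "significant", "genes"]]
        for met in sorted(set(dropped)):
            logger.info("metabolite %s dropped: no member gene with statistics", met)
        return ReporterResults(self, tables, n_perm=n_perm, seed=seed, dropped=sorted(set(dropped)))


@dataclass
class ReporterResults:
    model: ReporterAnalysis
    tables: dict[str, pd.DataFrame]
    n_perm: int
    seed: int | None
    dropped: list[str] = field(default_factory=list)

    def table(self, cls: str) -> pd.DataFrame:
        return self.tables[cls]

    def summary(self, top: int = 10) -> str:
        lines = [
            "Reporter-metabolite enrichment",
            "=" * 46,
            f"metabolite sets tested: {len(self.model.sets)}",
            f"permutations:           {self.n_perm}",
            f"dropped (no stats):     {len(self.dropped)}",
        ]
        for cls in CLASSES:
            df = self.tables[cls]
            lines.append("-" * 46)
            lines.append(f"class {cls}: {int(df['significant'].sum()) if len(df) else 0} significant")
            head = df.sort_values("pvalue").head(top)
            for met, row in head.iterrows():
                lines.append(
                    f"  {met:<18} k={int(row.k):<3} Z={row.z_corrected:6.2f} "
                    f"p={row.pvalue:.4g} padj={row.padj:.4g}"
                )
        return "\n".join(lines)

    def to_tsv(self, directory, prefix: str = "reporter") -> list[str]:
        import os

        paths = []
        for cls, df in self.tables.items():
            path = os.path.join(directory, f"{prefix}_{cls}.tsv")
            df.to_csv(path, sep="\t")
            paths.append(path)
        return paths


def reporter_analysis(
    stats: GeneStats,
    sets: dict[str, set[str]],
    n_perm: int = 10_000,
    seed: int | None = None,
    **kwargs,
) -> ReporterResults:
    """Functional wrapper over :class:`ReporterAnalysis`."""
    return ReporterAnalysis(stats, sets).fit(n_perm=n_perm, seed=seed, **kwargs)
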