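"""Resilience and susceptibility gene signatures from pairwise DEG tables.

The three-group design (control C, stress-low SL = resilient, stress-high
SH = vulnerable) yields three pairwise DEG tables. Genes shared between the
C-vs-SL and SL-vs-SH tables separate resilient animals from *both* other
groups and form the resilience signature; genes shared between C-vs-SH and
SL-vs-SH mark vulnerable animals against both other groups and form the
susceptibility signature. Overlaps are set-based and ignore fold-change
direction by default; a direction-consistent mode is available.

Gene identity is the pair (symbol, normalized full name). Symbol-only
matching is wrong for published rodent tables, where one symbol can label two
distinct entries (e.g. ``Rpl19`` appearing both as "Ribosomal Protein L19"
and "Ribosomal protein L9-like"); normalization case-folds, collapses
whitespace and strips parenthetical aliases so that cosmetic differences do
not break a match.

DEGs whose significance hinges on a single extreme sample are flagged by a
leave-one-out rule: remove the sample with the largest absolute within-group
z-score and re-test; if the gene is no longer significant, it is
outlier-driven and is typically disregarded.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from cbcsig import expression

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_symbol", "gene_name", "adjusted_p")


class SignatureError(ValueError):
    pass


class GeneIdentityKey(NamedTuple):
    """Identity of a DEG row: case-preserved symbol + normalized full name."""

    symbol: str
    name_normalized: str


def _strip_parentheticals(text: str) -> str:
    out = []
    depth = 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def normalize_gene_name(name: str) -> str:
    """Case-fold, collapse whitespace, drop parenthetical aliases, trim punctuation."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    cleaned = _strip_parentheticals(str(name)).casefold()
    cleaned = " ".join(cleaned.split())
    return cleaned.strip(" ,;")


def gene_identity_key(symbol: str, name: str = "") -> GeneIdentityKey:
    """Build the identity key; two records match only if both components match."""
    if symbol is None or str(symbol).strip() == "":
        raise SignatureError("gene symbol must be non-empty")
    return GeneIdentityKey(str(symbol).strip(), normalize_gene_name(name))


@dataclass
class DEGTable:
    """Significant DEGs for one region and one pairwise contrast."""

    region: str  # "BLA" | "DG"
    contrast: str  # "C_vs_SL" | "C_vs_SH" | "SL_vs_SH"
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise SignatureError(f"DEG table missing column(s): {missing}")
        keys = self.keys()
        if len(keys) != len(self.records):
            raise SignatureError(
                f"{self.region}/{self.contrast}: duplicate gene identity keys"
            )

    def keys(self) -> set[GeneIdentityKey]:
        return {
            gene_identity_key(sym, name)
            for sym, name in zip(self.records["gene_symbol"], self.records["gene_name"])
        }

    def __len__(self) -> int:
        return len(self.records)


def parse_deg_table(path, region: str, contrast: str) -> DEGTable:
    """Read a DEG table TSV (gene_symbol, gene_name, adjusted_p [, extras]).

    Rows whose symbol is "Unknown" are retained but flagged unnamed in a
    ``named`` column. Duplicate identity keys are an error.
    """
    # keep_default_na: a literal "NA" gene name is data, not a missing value
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_symbol": str, "gene_name": str},
        keep_default_na=False, na_values=[],
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SignatureError(f"{path}: missing column(s) {missing}")
    df = df.copy()
    df["named"] = df["gene_symbol"].str.casefold() != "unknown"
    return DEGTable(region=region, contrast=contrast, records=df)


@dataclass
class SignatureSets:
    """The two overlap-derived signatures with their parent contrasts."""

    resilience: set[GeneIdentityKey]
    susceptibility: set[GeneIdentityKey]
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)


def _overlap(
    a: DEGTable, b: DEGTable, direction_consistent: bool
) -> set[GeneIdentityKey]:
    if a.region != b.region:
        raise SignatureError(f"region mismatch: {a.region} vs {b.region}")
    keys = a.keys() & b.keys()
    if direction_consistent:
        for table in (a, b):
            if "direction" not in table.records.columns:
                raise SignatureError(
                    "direction-consistent overlap needs a 'direction' column"
                )

        def dir_of(t: DEGTable) -> dict[GeneIdentityKey, str]:
            return {
                gene_identity_key(s, n): d
                for s, n, d in zip(
                    t.records["gene_symbol"],
                    t.records["gene_name"],
                    t.records["direction"],
                )
            }

        da, db = dir_of(a), dir_of(b)
        keys = {k for k in keys if da[k] == db[k]}
    return keys


def resilience_signature(
    deg_sl_vs_sh: DEGTable, deg_c_vs_sl: DEGTable, direction_consistent: bool = False
) -> set[GeneIdentityKey]:
    """Genes shared by the SL-vs-SH and C-vs-SL tables (same region)."""
    return _overlap(deg_sl_vs_sh, deg_c_vs_sl, direction_consistent)


def susceptibility_signature(
    deg_sl_vs_sh: DEGTable, deg_c_vs_sh: DEGTable, direction_consistent: bool = False
) -> set[GeneIdentityKey]:
    """Genes shared by the SL-vs-SH and C-vs-SH tables (same region)."""
    return _overlap(deg_sl_vs_sh, deg_c_vs_sh, direction_consistent)


def build_signatures(
    deg_sl_vs_sh: DEGTable,
    deg_c_vs_sl: DEGTable,
    deg_c_vs_sh: DEGTable,
    direction_consistent: bool = False,
) -> SignatureSets:
    res = resilience_signature(deg_sl_vs_sh, deg_c_vs_sl, direction_consistent)
    sus = susceptibility_signature(deg_sl_vs_sh, deg_c_vs_sh, direction_consistent)
    assert res <= deg_sl_vs_sh.keys() and res <= deg_c_vs_sl.keys()
    assert sus <= deg_sl_vs_sh.keys() and sus <= deg_c_vs_sh.keys()
    return SignatureSets(
        resilience=res,
        susceptibility=sus,
        provenance={
            "resilience": (deg_sl_vs_sh.contrast, deg_c_vs_sl.contrast),
            "susceptibility": (deg_sl_vs_sh.contrast, deg_c_vs_sh.contrast),
        },
    )


def _single_gene_wald_p(
    values: np.ndarray, groups: np.ndarray, dispersion: float | None = None
) -> float:
    """The DE engine's Wald p for a single gene's (normalized) expression values.

    ``dispersion`` supplies the engine's dispersion context (e.g. the common
    dispersion of the full DE run); without it there is no across-gene
    shrinkage target and the gene's own method-of-moments estimate is used.
    """
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise SignatureError("single-gene test requires exactly two groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    if dispersion is not None:
        phi = float(dispersion)
    else:
        var = (((a - ma) ** 2).sum() + ((b - mb) ** 2).sum()) / (na + nb - 2)
        m_pool = (na * ma + nb * mb) / (na + nb)
        phi = max((var - m_pool) / m_pool**2, 0.0) if m_pool > 0 else 0.0
    a_, b_ = ma + 0.5, mb + 0.5
    se = np.sqrt((1.0 / a_ + phi) / na + (1.0 / b_ + phi) / nb)
    z = (np.log(b_) - np.log(a_)) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def outlier_driven_filter(
    values,
    groups,
    alpha: float = 0.05,
    dispersion: float | None = None,
    tester: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> bool:
    """Leave-one-out check: is this DEG's significance driven by one sample?

    ``values`` are the gene's expression values (normalized counts or TPM)
    and ``groups`` the per-sample group labels of the tested contrast. The
    gene must be significant on the full data (precondition; an error
    otherwise). The single sample with the largest absolute within-group
    z-score is removed and the contrast re-tested with the DE engine's
    single-gene test (or ``tester``); the gene is flagged True when the
    re-test is no longer significant at ``alpha``. Pass ``dispersion`` to
    test under the full DE run's dispersion context (the own-gene estimate is
    otherwise badly inflated by the very outlier under scrutiny). If removal
    leaves a group with fewer than two samples the gene is flagged with a
    warning.
    """
    v = np.asarray(list(values), dtype=float)
    g = np.asarray(list(groups))
    if v.size != g.size:
        raise SignatureError("values and groups must have equal length")
    labels = sorted(set(g.tolist()))
    if len(labels) != 2 or any((g == lab).sum() < 2 for lab in labels):
        raise SignatureError("need exactly two groups with >= 2 samples each")
    if tester is not None:
        test = tester
    else:
        def test(values_, groups_):
            return _single_gene_wald_p(values_, groups_, dispersion=dispersion)

    p_full = test(v, g)
    if p_full >= alpha:
        raise SignatureError(
            f"outlier filter precondition failed: gene not significant (p={p_full:.3g})"
        )
    z = np.empty_like(v)
    for lab in labels:
        mask = g == lab
        sd = v[mask].std(ddof=1)
        z[mask] = 0.0 if sd == 0 else (v[mask] - v[mask].mean()) / sd
    drop = int(np.argmax(np.abs(z)))
    keep = np.ones(v.size, dtype=bool)
    keep[drop] = False
    if any((g[keep] == lab).sum() < 2 for lab in labels):
        log.warning(
            "outlier filter: removing sample %d leaves a group with < 2 samples; "
            "flagging gene under a degenerate design", drop,
        )
        return True
    p_loo = test(v[keep], g[keep])
    flagged = p_loo >= alpha
    log.info(
        "outlier filter: removed sample %d (|z|=%.2f), p %0.3g -> %0.3g, flagged=%s",
        drop, abs(z[drop]), p_full, p_loo, flagged,
    )
    return bool(flagged)


@dataclass
class CorrelationResult:
    r: float
    p: float
    normality: dict[str, tuple[float, float]]


def expression_behavior_correlation(gene_values, composite_totals) -> CorrelationResult:
    """Pearson correlation of a gene's log2(TPM+1) values with composite scores.

    Also reports two normality tests on the expression values: Shapiro-Wilk
    and the D'Agostino-Pearson omnibus test (statistic, p) — the tests used
    to justify a parametric correlation on log-transformed TPM.
    """
    x = np.asarray(list(gene_values), dtype=float)
    y = np.asarray(list(composite_totals), dtype=float)
    if x.size != y.size:
        raise SignatureError("paired vectors must have equal length")
    if x.size < 3:
        raise SignatureError("need n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SignatureError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    sw = stats.shapiro(x)
    # D'Agostino-Pearson omnibus requires n >= 8 for the kurtosis component
    if x.size >= 8:
        dp = stats.normaltest(x)
        dp_stat, dp_p = float(dp.statistic), float(dp.pvalue)
    else:
        dp_stat, dp_p = float("nan"), float("nan")
    return CorrelationResult(
        r=float(r),
        p=float(p),
        normality={
            "shapiro_wilk": (float(sw.statistic), float(sw.pvalue)),
            "dagostino_pearson": (dp_stat, dp_p),
        },
    )


def load_reference_table(contrast: str, region: str = "DG") -> DEGTable:
    """Packaged dentate-gyrus DEG tables from a rat acute-severe-stress study.

    ``contrast`` is one of ``SL_vs_SH`` (40 DEGs), ``C_vs_SL`` (25 rows, one
    unnamed), ``C_vs_SH`` (5 DEGs). These ship as example/fixture data for
    the overlap logic.
    """
    files = {
        ("DG", "SL_vs_SH"): "table1_dg.tsv",
        ("DG", "C_vs_SL"): "table2_dg.tsv",
        ("DG", "C_vs_SH"): "table3_dg.tsv",
    }
    try:
        fname = files[(region, contrast)]
    except KeyError:
        raise SignatureError(f"no packaged table for region={region}, contrast={contrast}")
    ref = importlib.resources.files("cbcsig").joinpath("data", fname)
    with importlib.resources.as_file(ref) as path:
        return parse_deg_table(path, region=region, contrast=contrast)
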