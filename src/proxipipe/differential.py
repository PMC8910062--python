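"""Bait-normalized differential comparison of proximity interactomes.

Spectral counts scale with the abundance of the tagged bait itself, so
before comparing conditions the per-prey average counts are rescaled by the
bait's own spectral counts: ``normalized(prey, c) = avg_count(prey, c) *
self(ref) / self(c)``.  Fold changes are computed on these normalized counts
with a pseudocount so presence/absence calls stay finite, and preys are
classified as gained/lost at |log2FC| >= 1 between two conditions, or —
across a wild-type / mutant / mutant+drug triplet — as restored (present in
the wild-type network, lost in the mutant, regained under drug), attenuated
(elevated in the mutant, reduced by drug) or non-responsive (elevated in the
mutant, unmoved by drug).

Volcano statistics use a Welch t-test on log2(count + 1) across replicate
runs; a generic hypergeometric over-representation test against
user-supplied category annotations stands in for external GO services.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import SpectralCountTable
from .errors import ParseError, ValidationError
from .scoring import ScoredInteraction

PSEUDOCOUNT = 0.5
FC_THRESHOLD = 1.0
FLAG_THRESHOLD = 0.4


@dataclass(frozen=True)
class BaitAbundance:
    """Average spectral counts of the bait protein itself in one condition."""

    bait_condition: str
    self_count_mean: float

    def __post_init__(self):
        if not self.self_count_mean > 0:
            raise ValidationError(
                f"bait not detected in {self.bait_condition!r} "
                f"(self count {self.self_count_mean})"
            )


def bait_abundance_from_table(
    table: SpectralCountTable, bait_condition: str, bait_gene: str
) -> BaitAbundance:
    """Mean self-count of *bait_gene* across the runs of a condition."""
    runs = table.run_ids(bait_condition)
    if not runs:
        raise ValidationError(f"no runs for condition {bait_condition!r}")
    mat = table.count_matrix(runs)
    if bait_gene not in mat.index or mat.loc[bait_gene].sum() == 0:
        raise ValidationError(
            f"bait not detected: {bait_gene!r} absent from {bait_condition!r} runs"
        )
    return BaitAbundance(bait_condition, float(mat.loc[bait_gene].mean()))


def normalize_by_bait(
    scored_by_condition: Mapping[str, Sequence[ScoredInteraction]],
    abundances: Mapping[str, BaitAbundance | float],
    reference_condition: str,
) -> pd.DataFrame:
    """Prey x condition matrix of bait-normalized average counts.

    Counts in condition ``c`` are scaled by ``self(ref) / self(c)``; the
    reference condition is left unchanged.  Preys absent from a condition
    get 0.
    """

    def self_count(cond: str) -> float:
        if cond not in abundances:
            raise ValidationError(f"bait not detected: no abundance for {cond!r}")
        ab = abundances[cond]
        val = ab.self_count_mean if isinstance(ab, BaitAbundance) else float(ab)
        if not val > 0:
            raise ValidationError(f"bait not detected: zero self count for {cond!r}")
        return val

    ref_self = self_count(reference_condition)
    columns = {}
    for cond, scored in scored_by_condition.items():
        factor = ref_self / self_count(cond)
        columns[cond] = {s.prey: s.avg_count * factor for s in scored}
    frame = pd.DataFrame(columns).fillna(0.0)
    return frame.sort_index()


def compute_log2fc(norm_ref: float, norm_alt: float, pseudocount: float = PSEUDOCOUNT) -> float:
    """log2((alt + pseudocount) / (ref + pseudocount)); pseudocount > 0."""
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be positive")
    return float(np.log2((norm_alt + pseudocount) / (norm_ref + pseudocount)))


def classify_pairwise(
    norm: pd.DataFrame,
    hc_ref: set[str],
    hc_alt: set[str],
    cond_ref: str,
    cond_alt: str,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Gained / lost / unchanged calls between two conditions.

    Operates on preys that are high confidence in at least one of the two
    conditions; others are excluded with a warning.  Boundary fold changes
    (exactly +-threshold) count as gained/lost.  Returns a frame indexed by
    prey with columns ``count_ref, count_alt, log2fc, label``.
    """
    for cond in (cond_ref, cond_alt):
        if cond not in norm.columns:
            raise ValidationError(f"condition {cond!r} absent from normalized matrix")
    preys = sorted(set(norm.index))
    eligible = [p for p in preys if p in hc_ref or p in hc_alt]
    skipped = len(preys) - len(eligible)
    if skipped:
        warnings.warn(
            f"{skipped} prey(s) high-confidence in neither condition; excluded"
        )
    rows = []
    for prey in eligible:
        ref = float(norm.at[prey, cond_ref]) if prey in norm.index else 0.0
        alt = float(norm.at[prey, cond_alt]) if prey in norm.index else 0.0
        fc = compute_log2fc(ref, alt, pseudocount)
        if fc >= fc_threshold:
            label = "gained"
        elif fc <= -fc_threshold:
            label = "lost"
        else:
            label = "unchanged"
        rows.append((prey, ref, alt, fc, label))
    return pd.DataFrame(
        rows, columns=["prey", "count_ref", "count_alt", "log2fc", "label"]
    ).set_index("prey")


def classify_restored(
    norm: pd.DataFrame,
    hc: Mapping[str, set[str]],
    wt: str,
    mut: str,
    mut_drug: str,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Drug-response classes across a WT / mutant / mutant+drug triplet.

    restored
        In the WT high-confidence network, lost in the mutant (either not
        high confidence there or down >= fc_threshold in log2), and back in
        the mutant+drug network.
    attenuated
        Elevated in the mutant vs WT (log2FC >= +threshold) and reduced by
        the drug (log2FC mutant+drug vs mutant <= -threshold).
    non_responsive
        Elevated in the mutant and essentially unmoved by the drug
        (|log2FC| < threshold).
    other
        Everything else.

    Classes are assigned in that order of precedence, so a prey carries
    exactly one label and restored/attenuated are disjoint by construction.
    """
    for cond in (wt, mut, mut_drug):
        if cond not in norm.columns:
            raise ValidationError(f"missing condition {cond!r}")
        if cond not in hc:
            raise ValidationError(f"missing high-confidence set for {cond!r}")
    preys = sorted(p for p in norm.index if any(p in hc[c] for c in (wt, mut, mut_drug)))
    rows = []
    for prey in preys:
        v_wt = float(norm.at[prey, wt])
        v_mut = float(norm.at[prey, mut])
        v_drug = float(norm.at[prey, mut_drug])
        fc_mut_wt = compute_log2fc(v_wt, v_mut, pseudocount)
        fc_drug_mut = compute_log2fc(v_mut, v_drug, pseudocount)
        if (
            prey in hc[wt]
            and (prey not in hc[mut] or fc_mut_wt <= -fc_threshold)
            and prey in hc[mut_drug]
        ):
            label = "restored"
        elif fc_mut_wt >= fc_threshold and fc_drug_mut <= -fc_threshold:
            label = "attenuated"
        elif fc_mut_wt >= fc_threshold and abs(fc_drug_mut) < fc_threshold:
            label = "non_responsive"
        else:
            label = "other"
        rows.append((prey, v_wt, v_mut, v_drug, fc_mut_wt, fc_drug_mut, label))
    out = pd.DataFrame(
        rows,
        columns=["prey", "count_wt", "count_mut", "count_mut_drug",
                 "log2fc_mut_wt", "log2fc_drug_mut", "label"],
    ).set_index("prey")
    assert not (
        set(out.index[out["label"] == "restored"])
        & set(out.index[out["label"] == "attenuated"])
    ), "restored and attenuated must be disjoint"
    return out


def volcano_stats(
    table: SpectralCountTable,
    cond_a: str,
    cond_b: str,
    flag_threshold: float = FLAG_THRESHOLD,
    scale: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-prey log2 fold change and Welch t-test across replicate runs.

    Counts are optionally rescaled per condition (bait normalization) via
    *scale*, then transformed as log2(count + 1).  The fold change is the
    difference of condition means on that scale (b minus a); the p-value is
    a two-sided Welch t-test over replicate runs.  Preys move into the
    ``green`` flag at log2FC >= +flag_threshold (higher in b) and ``red`` at
    <= -flag_threshold (lower in b).
    """
    runs_a = table.run_ids(cond_a)
    runs_b = table.run_ids(cond_b)
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValidationError("need >= 2 replicate runs per condition")
    mat_a = table.count_matrix(runs_a)
    mat_b = table.count_matrix(runs_b)
    preys = sorted(set(mat_a.index) | set(mat_b.index))
    mat_a = mat_a.reindex(preys, fill_value=0)
    mat_b = mat_b.reindex(preys, fill_value=0)
    fa = scale.get(cond_a, 1.0) if scale else 1.0
    fb = scale.get(cond_b, 1.0) if scale else 1.0
    ya = np.log2(mat_a.to_numpy() * fa + 1.0)
    yb = np.log2(mat_b.to_numpy() * fb + 1.0)

    log2fc = yb.mean(axis=1) - ya.mean(axis=1)
    tiny = np.finfo(float).tiny
    pvals = np.ones(len(preys))
    res = stats.ttest_ind(yb, ya, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    zero_var = (ya.std(axis=1) == 0) & (yb.std(axis=1) == 0)
    equal_mean = np.isclose(log2fc, 0.0)
    pvals[zero_var & equal_mean] = 1.0
    degenerate = zero_var & ~equal_mean
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} prey(s) with zero variance but unequal "
            "means; p floored to machine minimum"
        )
        pvals[degenerate] = tiny
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    pvals = np.clip(pvals, tiny, 1.0)

    flag = np.where(
        log2fc >= flag_threshold, "green", np.where(log2fc <= -flag_threshold, "red", "none")
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "neg_log10_p": -np.log10(pvals),
            "flag": flag,
        },
        index=pd.Index(preys, name="prey"),
    )


@dataclass(frozen=True)
class CategoryAnnotation:
    """One functional category (e.g. a GO term) and its member genes."""

    category_id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"empty gene set for category {self.category_id!r}")


def read_annotation(path) -> list[CategoryAnnotation]:
    """Read categories from a two-column (category, gene) TSV with header,
    or a GMT file (category, label, gene, gene, ...; extension .gmt)."""
    path = Path(path)
    cats: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    if path.suffix.lower() == ".gmt":
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ParseError("GMT line needs >= 3 fields", path=path, line=lineno)
                cats.setdefault(parts[0], set()).update(g.upper() for g in parts[2:] if g)
                labels[parts[0]] = parts[1]
    else:
        with open(path, "r", encoding="utf-8") as fh:
            fh.readline()  # header
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ParseError("expected 2 columns", path=path, line=lineno)
                cats.setdefault(parts[0], set()).add(parts[1].upper())
                labels.setdefault(parts[0], parts[0])
    return [
        CategoryAnnotation(cid, labels[cid], frozenset(genes))
        for cid, genes in sorted(cats.items())
    ]


def enrichment_test(
    selected: set[str],
    annotation: Sequence[CategoryAnnotation],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per category.

    For a category with K genes in the universe and k of them among the N
    selected genes, the p-value is P(X >= k) under sampling N genes without
    replacement from the universe of size M.  Benjamini-Hochberg q-values
    are reported alongside the raw p-values.
    """
    if not universe:
        raise ValidationError("empty universe")
    universe = {g.upper() for g in universe}
    selected = {g.upper() for g in selected}
    if not selected <= universe:
        raise ValidationError("selected genes must be a subset of the universe")
    M, N = len(universe), len(selected)
    rows = []
    for cat in annotation:
        members = cat.genes & universe
        K = len(members)
        k = len(members & selected)
        expected = N * K / M
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append((cat.category_id, cat.label, k, K, expected, p))
    frame = pd.DataFrame(
        rows, columns=["category_id", "label", "overlap", "category_size", "expected", "p_value"]
    )
    if len(frame):
        frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["q_value"] = []
    return frame.set_index("category_id")
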