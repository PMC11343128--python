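"""Statistical workflows for allelic imbalance across individuals.

The layer above :mod:`snase.betabin`: orienting haplotype-level counts by
an anchor SNP so every individual's "reference" means the same physical
allele, per-feature beta-binomial tests (pseudobulk and mixed),
differential tests, the peak-vs-rest-of-gene comparison, Fisher 2x2
comparisons, multiple-testing adjustment, and the allele-permutation
machinery used to check type-I-error calibration.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ase_counting import pseudobulk
from .betabin import BetaBinomialMixedModel, BetaBinomialModel, BetaBinomialResults
from .types import AseCountTable, PhasedVariant

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "feature_id", "n_individuals", "n_total", "effect", "se", "z", "p",
    "rho", "sigma_b", "converged", "flag",
]


# ---------------------------------------------------------------------------
# phase orientation


def orient_by_snp(
    hap_counts: pd.DataFrame,
    variants: Sequence[PhasedVariant],
    anchor_snp: str,
) -> pd.DataFrame:
    """Re-label per-individual haplotype counts by an anchor SNP's phase.

    ``hap_counts`` has one row per individual with haplotype-1/2 counts in
    ``n_ref``/``n_alt`` position (the phased-mode output of the counting
    layer). For genotype ``0|1`` haplotype 1 carries the reference base and
    the counts stand; for ``1|0`` they are swapped; individuals not
    heterozygous at the anchor SNP are dropped.
    """
    by_key = {v.key: v for v in variants}
    if anchor_snp not in by_key:
        raise KeyError(f"anchor SNP {anchor_snp} absent from the supplied variants")
    anchor = by_key[anchor_snp]
    rows = []
    for r in hap_counts.itertuples():
        gt = anchor.genotype(r.individual_id)
        if gt == "0|1":
            rows.append((r.Index, False))
        elif gt == "1|0":
            rows.append((r.Index, True))
    if not rows:
        logger.warning("no individuals heterozygous at %s; empty orientation", anchor_snp)
        return hap_counts.iloc[0:0].copy()
    idx = [i for i, _ in rows]
    swap = np.array([s for _, s in rows])
    out = hap_counts.loc[idx].copy().reset_index(drop=True)
    ref = out["n_ref"].to_numpy().copy()
    alt = out["n_alt"].to_numpy().copy()
    out["n_ref"] = np.where(swap, alt, ref)
    out["n_alt"] = np.where(swap, ref, alt)
    return out


# ---------------------------------------------------------------------------
# per-feature model fits


def fit_betabin_pseudobulk(
    data: pd.DataFrame, formula: str = "1", **fit_kwargs
) -> BetaBinomialResults:
    """Beta-binomial regression on per-individual oriented counts.

    One row per individual with ``n_ref``/``n_alt``; ``formula`` gives the
    fixed effects (RHS only), default intercept-only.
    """
    data = data[(data["n_ref"] + data["n_alt"]) > 0]
    model = BetaBinomialModel.from_formula(formula, data)
    return model.fit(**fit_kwargs)


def fit_betabin_mixed(
    data: pd.DataFrame,
    formula: str = "1",
    groups: str = "individual_id",
    n_quad: int = 20,
    **fit_kwargs,
) -> BetaBinomialResults:
    """Mixed beta-binomial fit on cell-level counts with an individual random intercept."""
    data = data[(data["n_ref"] + data["n_alt"]) > 0]
    model = BetaBinomialMixedModel.from_formula(formula, data, groups=groups, n_quad=n_quad)
    return model.fit(**fit_kwargs)


def _as_df(table: Union[AseCountTable, pd.DataFrame]) -> pd.DataFrame:
    return table.df if isinstance(table, AseCountTable) else table


def test_allelic_imbalance(
    table: Union[AseCountTable, pd.DataFrame],
    model: str = "pseudobulk",
    formula: str = "1",
    *,
    coef: Union[int, str] = 0,
    min_individuals: int = 2,
    min_total: int = 5,
    n_quad: int = 20,
) -> pd.DataFrame:
    """Per-feature allelic-imbalance test over a long-format count table.

    Pseudobulk tables are fitted as-is; for ``model="mixed"`` the table
    must be cell level and ``individual_id`` becomes the grouping factor.
    Features with fewer than ``min_individuals`` informative individuals
    or fewer than ``min_total`` phased molecules are reported untested.
    ``coef`` selects the coefficient whose Wald test is reported
    (default the intercept, i.e. the imbalance effect itself).
    """
    df = _as_df(table)
    if model == "pseudobulk" and (df["unit_id"] != df["individual_id"]).any():
        agg = {"n_ref": "sum", "n_alt": "sum", "n_ambiguous": "sum"}
        for c in df.columns:
            if c not in agg and c not in ("unit_id", "individual_id", "feature_id"):
                agg[c] = "first"
        df = df.groupby(["individual_id", "feature_id"], as_index=False).agg(agg)
        df["unit_id"] = df["individual_id"]
    out = []
    for feature_id, fdf in df.groupby("feature_id", sort=True):
        fdf = fdf[(fdf["n_ref"] + fdf["n_alt"]) > 0]
        n_ind = fdf["individual_id"].nunique()
        n_total = int((fdf["n_ref"] + fdf["n_alt"]).sum())
        row = {
            "feature_id": feature_id,
            "n_individuals": n_ind,
            "n_total": n_total,
            "effect": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
            "rho": np.nan, "sigma_b": np.nan, "converged": False, "flag": "",
        }
        if n_ind < min_individuals or n_total < min_total:
            row["flag"] = "insufficient_data"
            out.append(row)
            continue
        try:
            if model == "pseudobulk":
                res = fit_betabin_pseudobulk(fdf, formula)
            elif model == "mixed":
                res = fit_betabin_mixed(fdf, formula, n_quad=n_quad)
            else:
                raise ValueError(f"unknown model {model!r}")
        except (ValueError, np.linalg.LinAlgError) as exc:
            row["flag"] = f"fit_error:{exc}"
            out.append(row)
            continue
        j = coef if isinstance(coef, int) else res.exog_names.index(coef)
        row.update(
            effect=res.params[j], se=res.bse[j], z=res.zvalues[j], p=res.pvalues[j],
            rho=res.rho, sigma_b=res.sigma_b if res.sigma_b is not None else np.nan,
            converged=res.converged, flag=",".join(res.flags),
        )
        out.append(row)
    return pd.DataFrame(out, columns=RESULT_COLUMNS)


def test_differential_imbalance(
    table: Union[AseCountTable, pd.DataFrame],
    condition: str = "condition",
    model: str = "pseudobulk",
    **kwargs,
) -> pd.DataFrame:
    """Differential allelic imbalance between conditions.

    Same machinery as the plain test but with formula ``~condition``; the
    reported Wald test is for the condition coefficient while the
    intercept is still estimated.
    """
    df = _as_df(table)
    if df[condition].nunique() < 2:
        raise ValueError("differential test needs at least two condition levels")
    levels = sorted(df[condition].unique())
    coef_name = f"{condition}[T.{levels[1]}]"
    return test_allelic_imbalance(df, model=model, formula=condition, coef=coef_name, **kwargs)


def test_peak_vs_gene(
    peak_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    model: str = "pseudobulk",
    **kwargs,
) -> Tuple[Optional[BetaBinomialResults], dict]:
    """Does a peak's allelic ratio differ from the rest of its gene?

    Inputs are per-unit counts for one peak and its host gene.
    Rest-of-gene counts are the gene's minus the peak's (clamped at zero
    with a warning when inconsistent); the stacked observations are
    fitted with an is-peak indicator whose Wald p is the answer.
    Returns ``(results, info)``; results is None when the comparison is
    degenerate (e.g. the peak holds all the gene's counts).
    """
    merged = peak_counts.merge(
        gene_counts, on=["unit_id", "individual_id"], suffixes=("_peak", "_gene"), how="inner"
    )
    info: dict = {"n_units": len(merged), "clamped": 0, "skipped": None}
    if merged.empty:
        info["skipped"] = "no_shared_units"
        return None, info
    rest_ref = merged["n_ref_gene"] - merged["n_ref_peak"]
    rest_alt = merged["n_alt_gene"] - merged["n_alt_peak"]
    bad = (rest_ref < 0) | (rest_alt < 0)
    if bad.any():
        logger.warning("peak counts exceed gene counts for %d units; clamped", int(bad.sum()))
        info["clamped"] = int(bad.sum())
        rest_ref = rest_ref.clip(lower=0)
        rest_alt = rest_alt.clip(lower=0)
    stacked = pd.concat(
        [
            pd.DataFrame(
                {
                    "unit_id": merged["unit_id"], "individual_id": merged["individual_id"],
                    "n_ref": merged["n_ref_peak"], "n_alt": merged["n_alt_peak"], "is_peak": 1,
                }
            ),
            pd.DataFrame(
                {
                    "unit_id": merged["unit_id"], "individual_id": merged["individual_id"],
                    "n_ref": rest_ref, "n_alt": rest_alt, "is_peak": 0,
                }
            ),
        ],
        ignore_index=True,
    )
    stacked = stacked[(stacked["n_ref"] + stacked["n_alt"]) > 0]
    if stacked.loc[stacked.is_peak == 0].empty:
        info["skipped"] = "rest_of_gene_empty"
        return None, info
    if model == "pseudobulk":
        res = fit_betabin_pseudobulk(stacked, "is_peak", **kwargs)
    else:
        res = fit_betabin_mixed(stacked, "is_peak", **kwargs)
    return res, info


# ---------------------------------------------------------------------------
# Fisher comparison and multiple testing


def fisher_compare(counts_a: Tuple[int, int], counts_b: Tuple[int, int]) -> Tuple[float, float]:
    """Two-sided Fisher's exact test comparing two (ref, alt) pairs.

    Returns (odds_ratio, p). An all-zero table gives p = 1 by convention.
    """
    table = np.array([list(counts_a), list(counts_b)])
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        logger.warning("all-zero 2x2 table; p set to 1")
        return np.nan, 1.0
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def fisher_compare_many(
    pairs: Mapping[str, Tuple[Tuple[int, int], Tuple[int, int]]]
) -> pd.DataFrame:
    """Fisher comparisons over many SNPs with Bonferroni FWER adjustment."""
    rows = []
    for key, (a, b) in pairs.items():
        odds, p = fisher_compare(a, b)
        rows.append({"feature_id": key, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    df["fwer"] = adjust_pvalues(df["p"].to_numpy(), method="bonferroni")
    return df


def adjust_pvalues(pvals, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjustment; NaNs propagate."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[method]
        out[ok] = multipletests(p[ok], method=key)[1]
    return out


# ---------------------------------------------------------------------------
# permutation calibration


def permute_alleles(
    table: Union[AseCountTable, pd.DataFrame], seed: int
) -> Union[AseCountTable, pd.DataFrame]:
    """Swap n_ref and n_alt with probability 1/2, per (individual, feature).

    The swap decision is shared by every row of an (individual, feature)
    pair, so cell-level tables stay internally consistent; row totals are
    untouched. Applying it to data with true imbalance manufactures a
    null dataset in which any symmetric test should fire ~5% of the time.
    """
    df = _as_df(table).copy()
    rng = np.random.default_rng(seed)
    keys = df[["individual_id", "feature_id"]].drop_duplicates().sort_values(
        ["individual_id", "feature_id"]
    )
    flips = rng.random(len(keys)) < 0.5
    flip_map = {
        (r.individual_id, r.feature_id): f for r, f in zip(keys.itertuples(), flips)
    }
    mask = np.array(
        [flip_map[(i, f)] for i, f in zip(df["individual_id"], df["feature_id"])]
    )
    ref = df["n_ref"].to_numpy().copy()
    alt = df["n_alt"].to_numpy().copy()
    df.loc[:, "n_ref"] = np.where(mask, alt, ref)
    df.loc[:, "n_alt"] = np.where(mask, ref, alt)
    return AseCountTable(df) if isinstance(table, AseCountTable) else df


def fpr_experiment(
    table: Union[AseCountTable, pd.DataFrame],
    n_perms: int = 100,
    test: str = "pseudobulk",
    *,
    alpha: float = 0.05,
    seed: int = 0,
    min_individuals: int = 2,
    min_total: int = 5,
) -> Tuple[np.ndarray, float]:
    """Empirical false-positive-rate calibration by allele permutation.

    Each replicate permutes ref/alt per (individual, feature), runs the
    chosen allelic-imbalance test on every feature, and records the
    fraction of tested features with p below ``alpha``. Returns the
    per-replicate fractions and their median; a well-calibrated test
    should sit near ``alpha``.
    """
    df = _as_df(table)
    if test == "pseudobulk" and df["unit_id"].nunique() != df["individual_id"].nunique():
        df = pseudobulk(AseCountTable(df)).df
    seeds = np.random.SeedSequence(seed).generate_state(n_perms) % (2**31)
    fractions = np.empty(n_perms)
    for i in range(n_perms):
        perm = permute_alleles(df, int(seeds[i]))
        res = test_allelic_imbalance(
            perm, model=test, min_individuals=min_individuals, min_total=min_total
        )
        tested = res[~np.isnan(res["p"])]
        fractions[i] = float((tested["p"] < alpha).mean()) if len(tested) else np.nan
    return fractions, float(np.nanmedian(fractions))


def downsample_individuals(
    table: Union[AseCountTable, pd.DataFrame], k: int, seed: int
) -> Tuple[Union[AseCountTable, pd.DataFrame], list]:
    """Uniformly subsample ``k`` individuals without replacement (seeded).

    Returns the restricted table plus the selected ids so the same
    subset can be reused across parallel analyses.
    """
    df = _as_df(table)
    individuals = sorted(df["individual_id"].unique())
    if not (0 < k <= len(individuals)):
        raise ValueError(f"k must be in 1..{len(individuals)}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(individuals, size=k, replace=False))
    logger.info("downsampled individuals: %s", chosen)
    sub = df[df["individual_id"].isin(chosen)].reset_index(drop=True)
    return (AseCountTable(sub) if isinstance(table, AseCountTable) else sub), list(chosen)
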