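"""End-to-end pipeline: chain the three analysis strands and write reports.

Each stage runs only when its input table is present; outputs are JSON
summaries, TSV matrices and Newick trees under the output directory, plus a
run log recording every threshold and seed used.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import biodistance as bd
from . import io as npio
from . import isotopes as iso
from . import mortuary as mt
from .records import AnalysisConfig

logger = logging.getLogger("necropop")

__all__ = ["run_pipeline", "isotope_stage", "biodistance_stage", "mortuary_stage"]


def _build_local_range(bone_ratios, config: AnalysisConfig) -> iso.LocalRange:
    if config.local_range_bounds is not None:
        lo, hi = config.local_range_bounds
        return iso.LocalRange(lo, hi, (("configured", lo, hi),))
    mean, two_sigma = iso.summarize_ratios(bone_ratios)
    d = config.baseline_round_decimals
    if d is not None:
        mean, two_sigma = round(mean, d), round(two_sigma, d)
    return iso.estimate_local_range(
        [("human_bone", mean, two_sigma), ("faunal", tuple(config.faunal_range))]
    )


def isotope_stage(samples, config: AnalysisConfig) -> dict:
    """Baseline summaries, local range, provenance and mobility calls."""
    bone = [s.ratio for s in samples if s.material == "bone"]
    enamel = [s.ratio for s in samples if s.material == "enamel"]
    bone_mean, bone_2s = iso.summarize_ratios(bone) if len(bone) >= 2 else (None, None)
    enamel_mean, enamel_2s = iso.summarize_ratios(enamel)
    local_range = _build_local_range(bone, config)
    by_ind = iso.group_by_individual(samples)
    calls = iso.classify_provenance(by_ind, local_range)
    mobility = []
    for ind, ss in by_ind.items():
        ranked = [s for s in ss if s.material == "enamel"]
        ranks = {iso.mineralization_rank(s.tooth) for s in ranked}
        if len(ranks) >= 2:
            mobility.append(
                iso.infer_mobility(ss, local_range, config.mobility_delta)
            )
    n_nonlocal = sum(1 for c in calls if c.status == "nonlocal")
    return {
        "baseline": {
            "bone_mean": bone_mean,
            "bone_two_sigma": bone_2s,
            "enamel_mean": enamel_mean,
            "enamel_two_sigma": enamel_2s,
            "local_range": [local_range.lower, local_range.upper],
            "components": [list(c) for c in local_range.components],
        },
        "provenance": [
            {
                "individual_id": c.individual_id,
                "status": c.status,
                "basis_tooth": c.basis_tooth,
                "direction": c.direction,
                "ratio": c.ratio,
            }
            for c in calls
        ],
        "mobility": [
            {
                "individual_id": m.individual_id,
                "early_tooth": m.early_tooth,
                "late_tooth": m.late_tooth,
                "early_ratio": m.early_ratio,
                "late_ratio": m.late_ratio,
                "category": m.category,
                "isotopically_distinct": m.isotopically_distinct,
            }
            for m in mobility
        ],
        "summary": {
            "n_individuals": len(calls),
            "n_nonlocal": n_nonlocal,
        },
    }


def biodistance_stage(groups, panel, config: AnalysisConfig) -> dict:
    """MMD matrix, significance flags, MDS coordinates and Ward tree."""
    matrix = bd.mmd_matrix(groups, panel)
    mds = bd.ClassicalMDS(n_components=2).fit(matrix.mmd)
    link = bd.ward_dendrogram(matrix.mmd)
    return {
        "matrix": matrix,
        "mds_coords": pd.DataFrame(
            mds.embedding_, index=matrix.groups, columns=["axis1", "axis2"]
        ),
        "mds_inertia": mds.explained_inertia_,
        "ward_linkage": link,
        "traits": list(panel),
    }


def mortuary_stage(matrix, config: AnalysisConfig) -> dict:
    """Distance/cluster, chi-square, AMOVA, CA, RF and VIF chain."""
    meta = matrix.metadata
    dist = mt.jaccard_matrix(matrix)
    link = mt.complete_linkage(dist.to_numpy())

    sex = meta["sex"].where(meta["sex"].isin(["male", "female", "probable_female"]))
    sex = sex.replace({"probable_female": "female"})
    age = meta["age_class"].where(meta["age_class"] != "unknown")
    origin = meta["origin_code"].map({0: "local", 2: "nonlocal"})

    rng = np.random.default_rng(config.seed)
    results: dict = {"jaccard": dist, "linkage": link, "chisq": {}, "amova": {}}
    for name, grouping in (("sex", sex), ("age", age), ("origin", origin)):
        if grouping.dropna().nunique() < 2:
            warnings.warn(f"grouping {name!r} has <2 classes; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, df, p, _ = mt.goods_by_group_chisq(matrix, grouping)
            res = mt.amova(
                dist,
                grouping,
                n_permutations=config.n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
        results["chisq"][name] = {"chi2": chi2, "df": df, "p": p}
        results["amova"][name] = res

    counts = matrix.presence.groupby(sex.fillna("unknown")).sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results["ca"] = mt.correspondence_analysis(counts.T)

    # RF for sex on adults with known sex, then VIF-pruned origin RF on the
    # sex-neutral variables.
    adult = meta["age_class"].isin(
        ["adolescent", "young_adult", "middle_adult", "old_adult"]
    )
    sex_subset = adult & sex.notna()
    results["rf_sex"] = None
    results["rf_origin"] = None
    if sex[sex_subset].nunique() == 2 and sex_subset.sum() >= 4:
        rf_sex = mt.random_forest_importance(
            matrix.presence[sex_subset],
            sex[sex_subset],
            n_trees=config.rf_n_trees,
            max_features=config.rf_max_features,
            seed=int(rng.integers(2**31 - 1)),
        )
        results["rf_sex"] = rf_sex
        sex_linked = rf_sex.importances[
            rf_sex.importances > config.rf_importance_cutoff
        ].index
        remaining = matrix.presence.drop(columns=list(sex_linked))
        remaining = remaining.loc[:, remaining.nunique() > 1]
        origin_subset = adult & origin.notna()
        if origin[origin_subset].nunique() == 2 and origin_subset.sum() >= 4:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                retained, removed, vifs = mt.vif_stepwise(
                    remaining[origin_subset], threshold=config.vif_threshold
                )
            results["vif"] = {"retained": retained, "removed": removed, "vifs": vifs}
            if len(retained) >= 2:
                results["rf_origin"] = mt.random_forest_importance(
                    remaining.loc[origin_subset, retained],
                    origin[origin_subset],
                    n_trees=config.rf_n_trees,
                    max_features=config.rf_max_features,
                    seed=int(rng.integers(2**31 - 1)),
                )
    return results


def run_pipeline(
    config: AnalysisConfig,
    out_dir,
    isotope_path=None,
    frequency_path=None,
    artifact_path=None,
) -> dict:
    """Run every stage whose input is given; write reports under ``out_dir``.

    Returns a dict of the in-memory stage results.  Missing inputs skip their
    stage with a warning rather than failing, so partial datasets still
    produce partial reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ran: dict = {}

    if isotope_path is not None:
        samples = npio.read_isotope_table(isotope_path)
        res = isotope_stage(samples, config)
        npio.write_json(res, out / "isotopes.json")
        ran["isotopes"] = res
    else:
        logger.warning("no isotope table; provenance stage skipped")

    if frequency_path is not None:
        groups, panel = npio.read_frequency_table(frequency_path)
        res = biodistance_stage(groups, panel, config)
        res["matrix"].to_table5_layout().to_csv(out / "mmd_matrix.tsv", sep="\t")
        res["matrix"].significant.to_csv(out / "mmd_significant.tsv", sep="\t")
        res["mds_coords"].to_csv(out / "mds_coords.csv")
        npio.write_dendrogram(
            res["ward_linkage"], res["matrix"].groups, out / "mmd_ward.nwk"
        )
        ran["biodistance"] = res
    else:
        logger.warning("no frequency table; biodistance stage skipped")

    if artifact_path is not None:
        matrix = npio.read_artifact_matrix(artifact_path)
        res = mortuary_stage(matrix, config)
        res["jaccard"].to_csv(out / "jaccard.tsv", sep="\t")
        npio.write_dendrogram(
            res["linkage"], list(res["jaccard"].index), out / "goods_complete.nwk"
        )
        npio.write_json(res["chisq"], out / "chisq.json")
        npio.write_json(
            {k: v.to_dict() for k, v in res["amova"].items()}, out / "amova.json"
        )
        res["ca"].row_coords.to_csv(out / "ca_rows.csv")
        res["ca"].col_coords.to_csv(out / "ca_cols.csv")
        if res["rf_sex"] is not None:
            res["rf_sex"].importances.to_csv(out / "rf_sex_importance.csv")
            npio.write_json(
                {
                    "oob_error": res["rf_sex"].oob_error,
                    "confusion": res["rf_sex"].confusion.to_dict(),
                    "params": res["rf_sex"].params,
                },
                out / "rf_sex.json",
            )
        if res.get("vif") is not None:
            res["vif"]["vifs"].to_csv(out / "vif.csv")
        if res["rf_origin"] is not None:
            res["rf_origin"].importances.to_csv(out / "rf_origin_importance.csv")
            npio.write_json(
                {
                    "oob_error": res["rf_origin"].oob_error,
                    "confusion": res["rf_origin"].confusion.to_dict(),
                    "params": res["rf_origin"].params,
                },
                out / "rf_origin.json",
            )
        ran["mortuary"] = res
    else:
        logger.warning("no artifact matrix; mortuary stage skipped")

    npio.write_json(
        {
            "config": config.to_dict(),
            "stages_run": sorted(ran),
            "inputs": {
                "isotopes": str(isotope_path) if isotope_path else None,
                "frequencies": str(frequency_path) if frequency_path else None,
                "artifacts": str(artifact_path) if artifact_path else None,
            },
        },
        out / "run_log.json",
    )
    return ran
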