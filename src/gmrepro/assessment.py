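"""End-to-end assessment of inter- and intra-operator landmarking error.

Runs, in order: unbending, per-operator superimposition with outlier
screening (flags propagated to every operator's dataset), then five
tests on the cleaned data:

1. Do operators produce the same mean shape? Pooled GPA, PCA scores,
   pairwise repeated-measures Hotelling T² between operators, and a
   between-operator bgPCA with leave-one-out classification.
2. Does every operator detect the between-group (river) difference?
   Per-operator GPA, Procrustes ANOVA of shape on log centroid size +
   group, allometry adjustment, group ANOVA and group bgPCA/LOO.
3. Are the detected group differences consistent? Pairwise angles
   between operator-specific group-difference directions (bwgPC1),
   angles of those directions against inter-operator difference
   vectors, and bootstrapped group mean distances per operator.
4. What happens when operators each digitise only one group? The two
   most dissimilar operators' data are cross-merged by group and the
   group analyses repeated.
5. How large is intra-operator error? Per-operator trial-vs-trial
   repeated-measures tests, repeatability (ICC), and a nested variance
   partition (individual / individual:operator / residual) on the
   replicate subset.
"""
from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from typing import Mapping

import numpy as np
import pandas as pd

from .base import ShapeDataset
from .gpa import gpa, unbend
from .ordination import BetweenGroupPCA, pca
from .anova import ProcrustesANOVA, allometry_adjust, nested_variance_partition, repeatability
from .vectors import (
    angle_test,
    bootstrap_group_distance,
    operator_difference_vector,
    repeated_measures_t2,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AssessmentConfig:
    """Run configuration; ``fast`` and ``paper`` profiles set the
    permutation and bootstrap counts."""

    n_permutations: int = 999
    n_bootstrap: int = 500
    seed: int = 0
    outlier_k_iqr: float = 1.5
    propagate_outliers: bool = True
    unbend_degree: int = 2
    slide: bool = True
    merge_pair: tuple | None = None   # override the automatic worst pair

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "AssessmentConfig":
        return cls(n_permutations=999, n_bootstrap=500, seed=seed, **kw)

    @classmethod
    def paper(cls, seed: int = 0, **kw) -> "AssessmentConfig":
        return cls(n_permutations=10_000, n_bootstrap=10_000, seed=seed, **kw)


@dataclasses.dataclass
class AssessmentReport:
    """Structured results of the five tests (plain dict/DataFrame content)."""

    preliminary: dict
    test1: dict
    test2: dict
    test3: dict
    test4: dict
    test5: dict
    config: dict
    seeds: dict

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        out = ["# Landmarking-error assessment", ""]
        out += ["## Preliminary", "",
                f"- outliers removed: {self.preliminary['outliers_removed']}",
                f"- specimens analysed: {self.preliminary['n_specimens']}", ""]
        out += ["## Test 1 — operator mean shapes", "",
                _md_table(pd.DataFrame(self.test1["pairwise"])), "",
                f"Between-operator LOO classification accuracy: "
                f"{self.test1['cv_accuracy']:.3f}", ""]
        rows = []
        for op, t in self.test2["river_anova"].items():
            rows.append({"Operator": op, **t})
        out += ["## Test 2 — group differences per operator", "",
                _md_table(pd.DataFrame(rows)), ""]
        out += ["## Test 3 — consistency of group differences", "",
                "Angles (deg, lower) / p-values (upper):", "",
                _md_table(pd.DataFrame(self.test3["angle_matrix"])), "",
                _md_table(pd.DataFrame(self.test3["bootstrap"]).T), ""]
        rows = [{"Dataset": k, **v} for k, v in self.test4["river_anova"].items()]
        out += ["## Test 4 — cross-merged operator datasets", "",
                f"Merged pair: {' vs '.join(self.test4['pair'])}", "",
                _md_table(pd.DataFrame(rows)), ""]
        out += ["## Test 5 — intra-operator error", "",
                _md_table(pd.DataFrame(self.test5["trial_tests"])), "",
                _md_table(pd.DataFrame(self.test5["repeatability"]).T), "",
                _md_table(pd.DataFrame(self.test5["nested_partition"])), ""]
        return "\n".join(out)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _plain(obj.to_dict(orient="list"))
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _md_table(df: pd.DataFrame) -> str:
    if not len(df):
        return "(empty)"
    def fmt(v):
        return f"{v:.5g}" if isinstance(v, (float, np.floating)) else str(v)
    cols = [str(c) for c in df.columns]
    rows = [[fmt(v) for v in rec] for rec in df.itertuples(index=False)]
    widths = [max(len(c), *(len(r[j]) for r in rows)) for j, c in enumerate(cols)]
    line = lambda cells: "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(cols), sep] + [line(r) for r in rows])


def _anova_row(results, term: str) -> dict:
    r = results.table.loc[term]
    return {
        "Df": int(r["Df"]), "SS": float(r["SS"]), "r2": float(r["Rsq"]),
        "F": float(r["F"]), "Z": float(r["Z"]), "P": float(r["P"]),
    }


def run_assessment(dataset: ShapeDataset, config: AssessmentConfig | None = None) -> AssessmentReport:
    """Run the five-test landmarking-error assessment on a dataset that
    contains at least two operators' digitisations of shared specimens
    (plus, optionally, replicate trials for the intra-operator test)."""
    config = config or AssessmentConfig()
    ss = np.random.SeedSequence(config.seed)

    def child_seed(label: str) -> int:
        h = zlib.crc32(label.encode())
        return int(np.random.SeedSequence(entropy=config.seed, spawn_key=(h,))
                   .generate_state(1)[0] % 2**31)

    seeds: dict = {}
    operators = sorted(dataset.factors["operator"].unique())
    rivers = sorted(dataset.factors["group"].unique())
    if len(operators) < 2:
        raise ValueError("the assessment needs at least two operators")

    # ---------------- preliminary: unbend, outliers ----------------
    ds = unbend(dataset, degree=config.unbend_degree) if dataset.scheme.unbend else dataset
    ds = ds.drop_excluded()

    flagged_ids: set = set()
    per_op_outliers = {}
    for op in operators:
        sub = ds.where(operator=op, trial=1)
        rep = gpa(sub, slide=config.slide).flag_outliers(config.outlier_k_iqr)
        ids = sub.factors.iloc[rep.flagged]["specimen_id"].tolist()
        per_op_outliers[op] = ids
        flagged_ids |= set(ids)
    if not config.propagate_outliers:
        flagged_ids = set()
    keep = ~ds.factors["specimen_id"].isin(flagged_ids).to_numpy()
    ds = ds.subset(keep)
    main = ds.where(trial=1)
    preliminary = {
        "per_operator_outliers": per_op_outliers,
        "outliers_removed": sorted(flagged_ids),
        "n_specimens": int(main.where(operator=operators[0]).n),
        "operators": operators,
        "groups": rivers,
    }

    # ---------------- Test 1: operator mean shapes ----------------
    pooled = gpa(main, slide=config.slide)
    pooled_pca = pca(pooled.flat)
    fac = pooled.factors
    # rows of each operator in shared specimen order
    shared = sorted(set.intersection(*[
        set(fac.loc[fac["operator"] == op, "specimen_id"]) for op in operators
    ]))
    op_rows = {}
    for op in operators:
        sub = fac[(fac["operator"] == op) & fac["specimen_id"].isin(shared)]
        op_rows[op] = sub.sort_values("specimen_id").index.to_numpy()

    pairwise = []
    distances = {}
    for a, b in itertools.combinations(operators, 2):
        ra, rb = op_rows[a], op_rows[b]
        t2 = repeated_measures_t2(pooled_pca.scores[ra], pooled_pca.scores[rb])
        dist = float(np.linalg.norm(
            pooled.flat[ra].mean(axis=0) - pooled.flat[rb].mean(axis=0)
        ))
        distances[(a, b)] = dist
        pairwise.append(
            {"Comparison": f"{a} vs {b}", "Euclidean dist.": dist, "T2": t2.T2,
             "F": t2.F, "df1": t2.df1, "df2": t2.df2, "P": t2.p}
        )
    op_bg = BetweenGroupPCA(pooled.flat, fac["operator"].to_numpy()).fit()
    test1 = {
        "pairwise": pairwise,
        "cv_accuracy": op_bg.cv_accuracy,
        "cv_table": op_bg.cv_table,
        "n_pc_axes": pooled_pca.n_components,
    }

    # ---------------- Test 2: per-operator group differences ----------------
    test2 = {"size_anova": {}, "river_anova": {}, "cv_accuracy": {}}
    river_vectors = {}
    adjusted_store = {}
    for op in operators:
        sub = main.where(operator=op)
        fit = gpa(sub, slide=config.slide)
        data = fit.factors.copy()
        data["log_cs"] = fit.log_centroid_sizes
        seeds[f"anova_size_{op}"] = child_seed(f"anova_size_{op}")
        size_res = ProcrustesANOVA(fit.flat, data, ["log_cs", "group"]).fit(
            n_permutations=config.n_permutations, seed=seeds[f"anova_size_{op}"]
        )
        adjusted = allometry_adjust(fit.flat, fit.log_centroid_sizes,
                                    data["group"].to_numpy())
        seeds[f"anova_river_{op}"] = child_seed(f"anova_river_{op}")
        river_res = ProcrustesANOVA(adjusted, data, ["group"]).fit(
            n_permutations=config.n_permutations, seed=seeds[f"anova_river_{op}"]
        )
        bg = BetweenGroupPCA(adjusted, data["group"].to_numpy()).fit()
        test2["size_anova"][op] = _anova_row(size_res, "log_cs")
        test2["river_anova"][op] = _anova_row(river_res, "group")
        test2["cv_accuracy"][op] = bg.cv_accuracy
        river_vectors[op] = bg.axes[0]
        adjusted_store[op] = (adjusted, data)

    # ---------------- Test 3: consistency across operators ----------------
    angle_matrix = []
    for a, b in itertools.combinations(operators, 2):
        res = angle_test(river_vectors[a], river_vectors[b])
        angle_matrix.append(
            {"pair": f"{a} vs {b}", "angle_deg": res.angle_deg, "P": res.p_value}
        )
    river_vs_operator = []
    for a, b in itertools.combinations(operators, 2):
        diff = operator_difference_vector(pooled.flat[op_rows[a]], pooled.flat[op_rows[b]])
        for op in operators:
            if np.linalg.norm(diff) < 1e-12:
                # no systematic difference between these operators: the
                # comparison direction is undefined
                river_vs_operator.append(
                    {"operator_pair": f"{a} vs {b}", "river_vector": op,
                     "angle_deg": None, "P": None}
                )
                continue
            res = angle_test(river_vectors[op], diff)
            river_vs_operator.append(
                {"operator_pair": f"{a} vs {b}", "river_vector": op,
                 "angle_deg": res.angle_deg, "P": res.p_value}
            )
    bootstrap = {}
    for op in operators:
        adjusted, data = adjusted_store[op]
        seeds[f"bootstrap_{op}"] = child_seed(f"bootstrap_{op}")
        bootstrap[op] = dataclasses.asdict(
            bootstrap_group_distance(adjusted, data["group"].to_numpy(),
                                     n_boot=config.n_bootstrap,
                                     seed=seeds[f"bootstrap_{op}"])
        )
    test3 = {"angle_matrix": angle_matrix, "river_vs_operator": river_vs_operator,
             "bootstrap": bootstrap}

    # ---------------- Test 4: cross-merged datasets ----------------
    test4 = {}
    if len(rivers) == 2:
        pair = config.merge_pair or max(distances, key=distances.get)
        merged_vectors = {}
        test4 = {"pair": list(pair), "river_anova": {}, "cv_accuracy": {},
                 "angle_vs_full": []}
        for opA, opB in (pair, pair[::-1]):
            name = f"{opA}-{rivers[0]} + {opB}-{rivers[1]}"
            sel = (
                ((main.factors["operator"] == opA) & (main.factors["group"] == rivers[0]))
                | ((main.factors["operator"] == opB) & (main.factors["group"] == rivers[1]))
            ).to_numpy()
            sub = main.subset(sel)
            fit = gpa(sub, slide=config.slide)
            data = fit.factors.copy()
            data["log_cs"] = fit.log_centroid_sizes
            adjusted = allometry_adjust(fit.flat, fit.log_centroid_sizes,
                                        data["group"].to_numpy())
            seeds[f"anova_merged_{name}"] = child_seed(f"anova_merged_{name}")
            res = ProcrustesANOVA(adjusted, data, ["group"]).fit(
                n_permutations=config.n_permutations,
                seed=seeds[f"anova_merged_{name}"],
            )
            bg = BetweenGroupPCA(adjusted, data["group"].to_numpy()).fit()
            test4["river_anova"][name] = _anova_row(res, "group")
            test4["cv_accuracy"][name] = bg.cv_accuracy
            merged_vectors[name] = bg.axes[0]
        (nameA, vA), (nameB, vB) = merged_vectors.items()
        res = angle_test(vA, vB)
        test4["angle_between_merged"] = {"angle_deg": res.angle_deg, "P": res.p_value}
        for name, v in merged_vectors.items():
            for op in operators:
                res = angle_test(v, river_vectors[op])
                test4["angle_vs_full"].append(
                    {"merged": name, "operator": op,
                     "angle_deg": res.angle_deg, "P": res.p_value}
                )

    # ---------------- Test 5: intra-operator error ----------------
    test5 = {}
    max_trial = int(ds.factors["trial"].max())
    if max_trial >= 2:
        counts = ds.factors.groupby("specimen_id")["trial"].max()
        rep_ids = set(counts[counts == max_trial].index)
        rep_ds = ds.where(specimen_id=rep_ids)
        trial_tests = []
        repeat = {}
        for op in operators:
            sub = rep_ds.where(operator=op)
            fit = gpa(sub, slide=config.slide)
            sub_pca = pca(fit.flat)
            f = fit.factors
            rows_by_trial = {
                t: f[f["trial"] == t].sort_values("specimen_id").index.to_numpy()
                for t in range(1, max_trial + 1)
            }
            for t1, t2 in itertools.combinations(range(1, max_trial + 1), 2):
                r = repeated_measures_t2(sub_pca.scores[rows_by_trial[t1]],
                                         sub_pca.scores[rows_by_trial[t2]])
                trial_tests.append(
                    {"Operator": op, "Trials": f"{t1} vs {t2}",
                     "Euclidean dist.": r.euclidean_distance, "T2": r.T2,
                     "F": r.F, "P": r.p}
                )
            rep_res = repeatability(fit.flat, f["specimen_id"].to_numpy(), m=max_trial)
            repeat[op] = {"R": rep_res.R, "anova_r2": rep_res.anova_r2,
                          "ms_among": rep_res.ms_among, "ms_within": rep_res.ms_within}
        pooled_rep = gpa(rep_ds, slide=config.slide)
        part = nested_variance_partition(
            pooled_rep.flat,
            pooled_rep.factors["specimen_id"].to_numpy(),
            pooled_rep.factors["operator"].to_numpy(),
        )
        test5 = {"trial_tests": trial_tests, "repeatability": repeat,
                 "nested_partition": part, "n_replicate_specimens": len(rep_ids)}
    else:
        logger.warning("no replicate trials found; intra-operator test skipped")

    return AssessmentReport(
        preliminary=preliminary, test1=test1, test2=test2, test3=test3,
        test4=test4, test5=test5,
        config=dataclasses.asdict(config), seeds=seeds,
    )
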