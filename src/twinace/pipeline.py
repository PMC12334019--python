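"""Config-driven orchestration of the full twin-study workflow.

Stages run in the study's order: simulate (or load) -> preprocess ->
descriptives/twin correlations -> assumption tests -> biometric model menu
with nested comparisons -> clustered association -> facet selection ->
ordered Cholesky decomposition -> report tables.  Every stage reads its
inputs from the output directory, so each is re-runnable in isolation, and
all numbers land in a single full-precision ``results.json`` from which the
two-decimal report tables are rendered.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import biometric as bio
from . import multivariate as mv
from .cohort import PHENO_PREFIX, TwinCohort
from .preprocess import residualize_age_sex
from .simulate import BiometricSpec, simulate_phenotypes

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "icc", "assumptions", "fit",
          "assoc", "decompose", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see ``from_yaml``)."""

    outdir: Path
    seed: int = 0
    cohort_file: str | None = None
    simulate: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    model: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw.get("stages", [])) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        return cls(outdir=Path(raw.get("outdir", "twinace_out")),
                   seed=int(raw.get("seed", 0)),
                   cohort_file=raw.get("cohort_file"),
                   simulate=raw.get("simulate", {}),
                   stages=list(raw.get("stages", STAGES)),
                   model=raw.get("model", {}),
                   association=raw.get("association", {}),
                   raw=raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(x) -> str:
    return "" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else f"{x:.2f}"


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.results: dict = {"seed": config.seed}
        res_path = self.out / "results.json"
        if res_path.exists():  # allow stage-wise re-runs from cache
            self.results = json.loads(res_path.read_text())

    # -- stage: simulate / load -------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg
        path = self.out / "cohort.csv"
        if cfg.cohort_file:
            cohort = TwinCohort.read_csv(cfg.cohort_file)
            cohort.write_csv(path)
            self.results["cohort"] = {"source": str(cfg.cohort_file)}
            return
        sim = dict(cfg.simulate)
        if not sim:
            raise PipelineError("config has neither cohort_file nor simulate")
        spec = BiometricSpec.from_standardized(
            a2=sim.get("a2", [0.5]), c2=sim.get("c2"), e2=sim.get("e2"),
            rA=sim.get("rA"), rC=sim.get("rC"), rE=sim.get("rE"),
            beta_age=sim.get("beta_age"), beta_sex=sim.get("beta_sex"),
            trait_names=sim.get("traits"))
        cohort = simulate_phenotypes(
            spec, n_mz=int(sim.get("n_mz", 431)), n_dz=int(sim.get("n_dz", 190)),
            n_singles=int(sim.get("n_singles", 0)),
            age_range=tuple(sim.get("age_range", (31.0, 55.0))),
            sex_ratio=float(sim.get("sex_ratio", 0.66)), seed=cfg.seed)
        cohort.write_csv(path)
        self.results["cohort"] = {"source": "simulated", "seed": cfg.seed,
                                  "n_records": len(cohort.data)}

    # -- stage: preprocess -------------------------------------------------
    def stage_preprocess(self) -> None:
        cohort = TwinCohort.read_csv(self.out / "cohort.csv")
        df = cohort.data.copy()
        for trait in cohort.phenotype_names:
            col = PHENO_PREFIX + trait
            df[col] = residualize_age_sex(df[col], df["age"], df["sex"])
        TwinCohort(df, meta=cohort.meta).write_csv(self.out / "processed.csv")

    def _processed(self) -> TwinCohort:
        path = self.out / "processed.csv"
        if not path.exists():
            raise PipelineError("run the preprocess stage first")
        return TwinCohort.read_csv(path)

    # -- stage: descriptives and twin correlations -------------------------
    def stage_icc(self) -> None:
        cohort = self._processed()
        raw = TwinCohort.read_csv(self.out / "cohort.csv")
        rows = []
        for trait in cohort.phenotype_names:
            col = PHENO_PREFIX + trait
            vals = raw.data[col].dropna()
            icc_mz = bio.intraclass_corr(cohort, trait, "MZ")
            icc_dz = bio.intraclass_corr(cohort, trait, "DZ")
            flags = bio.heuristic_components(icc_mz.r, icc_dz.r)
            rows.append({
                "trait": trait, "n": int(vals.size),
                "mz_pairs": icc_mz.n_pairs, "dz_pairs": icc_dz.n_pairs,
                "mean": float(vals.mean()), "sd": float(vals.std()),
                "r_mz": icc_mz.r, "se_mz": icc_mz.se,
                "r_dz": icc_dz.r, "se_dz": icc_dz.se,
                "A_suggested": flags.A_suggested,
                "C_suggested": flags.C_suggested,
                "D_suggested": flags.D_suggested})
        self.results["descriptives"] = rows

    # -- stage: assumption tests -------------------------------------------
    def stage_assumptions(self) -> None:
        cohort = self._processed()
        tests = bio.assumption_tests(cohort)
        self.results["assumptions"] = [
            {"constraint": t.nested_label, "delta_minus2LL": t.delta_minus2LL,
             "delta_df": t.delta_df, "p": t.p_value} for t in tests]

    # -- stage: biometric model menu ---------------------------------------
    def stage_fit(self) -> None:
        cohort = self._processed()
        mcfg = self.cfg.model
        menu = [tuple(m) for m in mcfg.get(
            "menu", [("A", "C", "E"), ("A", "E"), ("C", "E"), ("E",)])]
        parameterization = mcfg.get("parameterization", "cholesky")
        n_starts = int(mcfg.get("n_starts", 5))
        ci_method = mcfg.get("ci", "wald")
        data = bio.FimlData(cohort, include_singles=bool(
            mcfg.get("include_singles", True)))
        fits = {}
        for comps in menu:
            fits["".join(comps)] = bio.fit_biometric(
                data, components=comps, parameterization=parameterization,
                n_starts=n_starts, seed=self.cfg.seed)
        full_label = "".join(menu[0])
        full = fits[full_label]
        comparisons = []
        for label, fit in fits.items():
            if label == full_label:
                continue
            c = bio.compare_models(full, fit)
            comparisons.append({"full": full_label, "nested": label,
                                "delta_minus2LL": c.delta_minus2LL,
                                "delta_df": c.delta_df, "p": c.p_value,
                                "delta_aic": c.delta_aic,
                                "preferred": c.preferred})
        best_label = min(fits, key=lambda k: fits[k].aic)
        best = fits[best_label]
        table3 = []
        for i, trait in enumerate(best.data.traits):
            row = {"trait": trait}
            for comp in best.params.components:
                share = float(best.standardized[comp][i])
                row[f"{comp.lower()}2"] = share
                if ci_method == "profile":
                    lo, hi = bio.profile_ci(best, bio.share_quantity(comp, i))
                elif ci_method == "wald":
                    se = bio.wald_se(best, bio.share_quantity(comp, i))
                    lo, hi = share - 1.96 * se, share + 1.96 * se
                else:
                    lo = hi = float("nan")
                row[f"{comp.lower()}2_lo"], row[f"{comp.lower()}2_hi"] = lo, hi
            table3.append(row)
        self.results["model_fits"] = {
            label: {"minus2LL": f.minus2LL, "n_params": f.n_params,
                    "aic": f.aic, "converged": f.converged}
            for label, f in fits.items()}
        self.results["model_comparisons"] = comparisons
        self.results["best_model"] = best_label
        self.results["components"] = table3
        if {"A", "E"} <= set(best.params.components):
            rA, rE = mv.genetic_env_correlations(best)
            self.results["rA"] = rA.tolist()
            self.results["rE"] = rE.tolist()
        self._best_fit = best

    # -- stage: association -------------------------------------------------
    def stage_assoc(self) -> None:
        cohort = self._processed()
        acfg = self.cfg.association
        targets = acfg.get("targets") or cohort.phenotype_names[:1]
        predictors = acfg.get("predictors")
        if predictors is None:
            predictors = [t for t in cohort.phenotype_names
                          if t not in targets]
        threshold = float(acfg.get("threshold", 0.01))
        out = {}
        for target in targets:
            X = pd.DataFrame({
                p: cohort.data[PHENO_PREFIX + p] for p in predictors})
            X["age"] = cohort.data["age"]
            X["sex"] = cohort.data["sex"]
            res = assoc_mod.clustered_regression(
                cohort.data[PHENO_PREFIX + target], X,
                cohort.data["family_id"].to_numpy(),
                working=acfg.get("working", "exchangeable"))
            res.target = target
            selected = assoc_mod.select_facets(res, threshold)
            out[target] = {
                "table": res.table.reset_index()
                .rename(columns={"index": "predictor"})
                .to_dict(orient="records"),
                "marginal_r2": res.marginal_r2,
                "n_clusters": res.n_clusters,
                "selected": selected}
        self.results["association"] = out
        self.results["selection_threshold"] = threshold

    # -- stage: ordered Cholesky decomposition ------------------------------
    def stage_decompose(self) -> None:
        cohort = self._processed()
        if "association" not in self.results:
            raise PipelineError("run the assoc stage first")
        decomp = {}
        for target, res in self.results["association"].items():
            selected = res["selected"]
            if not selected:
                log.warning("no selected facets for %s; skipping", target)
                continue
            betas = {row["predictor"]: row["beta"] for row in res["table"]
                     if row["predictor"] in selected}
            ordering = mv.order_by_beta(betas, target)
            d = mv.cholesky_shared_unique(
                cohort, ordering, seed=self.cfg.seed,
                n_starts=int(self.cfg.model.get("n_starts", 5)))
            decomp[target] = {
                "ordering": d.ordering,
                "target_a2": d.target_total_a2,
                "target_e2": d.target_total_e2,
                "shared_a_pct": 100 * d.shared_a_fraction,
                "unique_a_pct": 100 * d.unique_a_fraction,
                "shared_e_pct": 100 * d.shared_e_fraction,
                "unique_e_pct": 100 * d.unique_e_fraction,
                "rA": d.rA.tolist(), "rE": d.rE.tolist()}
        self.results["decomposition"] = decomp

    # -- stage: report -------------------------------------------------------
    def stage_report(self) -> None:
        report_tables(self.results, self.out)

    # -- driver --------------------------------------------------------------
    def run(self) -> dict:
        for stage in self.cfg.stages:
            log.info("stage: %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                (self.out / "error.json").write_text(json.dumps(
                    {"stage": stage, "error": str(exc),
                     "type": type(exc).__name__}, indent=2))
                self._save()
                raise
            self._save()
        return self.results

    def _save(self) -> None:
        path = self.out / "results.json"
        path.write_text(json.dumps(self.results, indent=2, sort_keys=True,
                                   default=_jsonable))
        prov = {"seed": self.cfg.seed,
                "files": {p.name: _sha256(p) for p in sorted(self.out.glob("*"))
                          if p.name not in ("provenance.json",)
                          and p.is_file()}}
        (self.out / "provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, (np.generic,)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Run the configured stages; returns the full-precision results dict."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    return Pipeline(config).run()


def report_tables(results: dict, outdir) -> list[Path]:
    """Render fixed-layout delimited report tables (2-decimal formatting).

    Every printed number is the rounding of the corresponding full-precision
    value in ``results.json``; empty results yield header-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def write(name: str, header: list[str], rows: list[list[str]]):
        path = outdir / name
        lines = [",".join(header)] + [",".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    rows = [[d["trait"], str(d["n"]), f'{d["mz_pairs"]}/{d["dz_pairs"]}',
             _fmt(d["mean"]), _fmt(d["sd"]),
             f'{_fmt(d["r_mz"])} ({_fmt(d["se_mz"])})',
             f'{_fmt(d["r_dz"])} ({_fmt(d["se_dz"])})']
            for d in results.get("descriptives", [])]
    write("table1_descriptives.csv",
          ["trait", "n", "mz_dz_pairs", "mean", "sd", "rMZ_se", "rDZ_se"],
          rows)

    rows = [[a["constraint"], _fmt(a["delta_minus2LL"]), str(a["delta_df"]),
             f'{a["p"]:.3f}'] for a in results.get("assumptions", [])]
    write("assumption_tests.csv",
          ["constraint", "delta_minus2LL", "delta_df", "p"], rows)

    rows = [[c["full"], c["nested"], _fmt(c["delta_minus2LL"]),
             str(c["delta_df"]), f'{c["p"]:.3f}', _fmt(c["delta_aic"]),
             c["preferred"]] for c in results.get("model_comparisons", [])]
    write("model_comparisons.csv",
          ["full", "nested", "delta_minus2LL", "delta_df", "p", "delta_aic",
           "preferred"], rows)

    comp_rows = []
    for row in results.get("components", []):
        cells = [row["trait"]]
        for comp in ("a2", "c2", "e2"):
            if comp in row:
                cells.append(f'{_fmt(row[comp])} '
                             f'[{_fmt(row[comp + "_lo"])}; '
                             f'{_fmt(row[comp + "_hi"])}]')
            else:
                cells.append("")
        comp_rows.append(cells)
    write("table3_components.csv",
          ["trait", "a2_ci", "c2_ci", "e2_ci"], comp_rows)

    rows = []
    for target, res in results.get("association", {}).items():
        for r in res["table"]:
            rows.append([target, r["predictor"], _fmt(r["beta"]),
                         f'{r["p_raw"]:.4f}',
                         "" if r["p_fdr"] is None or not np.isfinite(r["p_fdr"])
                         else f'{r["p_fdr"]:.4f}',
                         _fmt(res["marginal_r2"])])
    write("table4_association.csv",
          ["target", "predictor", "beta", "p_raw", "p_fdr", "marginal_r2"],
          rows)

    rows = []
    for target, d in results.get("decomposition", {}).items():
        rows.append([target, ";".join(d["ordering"]),
                     _fmt(d["target_a2"]), _fmt(d["target_e2"]),
                     f'{d["shared_a_pct"]:.1f}', f'{d["unique_a_pct"]:.1f}',
                     f'{d["shared_e_pct"]:.1f}', f'{d["unique_e_pct"]:.1f}'])
    write("fig2_decomposition.csv",
          ["target", "ordering", "a2", "e2", "shared_a_pct", "unique_a_pct",
           "shared_e_pct", "unique_e_pct"], rows)

    rows = []
    for target, d in results.get("decomposition", {}).items():
        labels = d["ordering"]
        rA, rE = np.asarray(d["rA"]), np.asarray(d["rE"])
        t = len(labels) - 1
        for j in range(t):
            rows.append([target, labels[j], _fmt(rA[t, j]), _fmt(rE[t, j])])
    write("fig3_correlations.csv", ["target", "facet", "rA", "rE"], rows)
    return written
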