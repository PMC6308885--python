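"""End-to-end SGDC pipeline: inputs (or synthetic scenario) -> QC -> outlier
scans -> locus partition -> diversity tables -> SGDC tests -> files on disk.

The configuration is a flat nested mapping (YAML-friendly).  Top-level
keys:

``scenario``   parameters for the synthetic generator (mutually exclusive
               with ``inputs``),
``inputs``     paths: ``vcf``, ``community``, ``environment``,
               optional ``populations`` (two-column TSV individual/site),
``fixture``    path to a per-site reference diversity table (or
               ``"packaged"`` for the bundled *Carex gayana* table); when
               given alone, only the fixture-level SGDC report is run,
``qc``, ``scan``, ``sgdc``  stage settings,
``seed``       master seed, ``outdir`` output directory.

Identical config + seed produces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .simulate import ScenarioConfig, simulate_scenario
from .qc import QCConfig, apply_qc
from .scan import PCAOutlierScan, RDAOutlierScan, prescreen_environment, vif_check, build_partition
from .diversity import (expected_heterozygosity, cavalli_sforza_matrix,
                        bray_curtis, diversity_table)
from .stats import alpha_sgdc, mantel_test, subset_randomization, compare_marker_panels

__all__ = ["run_pipeline", "fixture_report"]

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def fixture_report(table: pd.DataFrame, tail: str = "one") -> pd.DataFrame:
    """Alpha-SGDC and marker-concordance report from a per-site reference
    diversity table (columns: richness, he_ds1..he_ds5, optional he_aflp
    and a 0/1 ``discordant`` column)."""
    rows = []
    he_cols = [c for c in table.columns if c.startswith("he_ds")]
    sub = table[table.get("discordant", 0) == 0]
    for c in he_cols:
        res = alpha_sgdc(table[c], table["richness"], tail=tail,
                         dataset=c.replace("he_", "").upper(), facet="richness")
        rows.append({"dataset": res.dataset, "facet": "richness", "scope": "all",
                     "r": res.r, "n": res.n, "p": res.p})
        if len(sub) >= 4 and len(sub) < len(table):
            res2 = alpha_sgdc(sub[c], sub["richness"], tail=tail,
                              dataset=res.dataset, facet="richness")
            rows.append({"dataset": res.dataset, "facet": "richness",
                         "scope": "concordant_sites", "r": res2.r, "n": res2.n, "p": res2.p})
    if "he_aflp" in table.columns:
        for c in he_cols:
            rep = compare_marker_panels(table[c], table["he_aflp"],
                                        exclude=table.index[table.get("discordant", 0) == 1])
            rows.append({"dataset": c.replace("he_", "").upper(), "facet": "marker_concordance",
                         "scope": "all", "r": rep["r"], "n": rep["n"], "p": np.nan})
            if "r_excluded" in rep:
                rows.append({"dataset": c.replace("he_", "").upper(),
                             "facet": "marker_concordance", "scope": "concordant_sites",
                             "r": rep["r_excluded"], "n": rep["n_excluded"], "p": np.nan})
    return pd.DataFrame(rows)


def _load_inputs(cfg: dict, seed: int):
    if "scenario" in cfg:
        sc = ScenarioConfig(**{**cfg["scenario"], "seed": cfg["scenario"].get("seed", seed)})
        gm, comm, env, truth = simulate_scenario(sc)
        return gm, comm, env, truth
    inputs = cfg["inputs"]
    pops = None
    if "populations" in inputs:
        pmap = pd.read_csv(inputs["populations"], sep="\t", index_col=0).iloc[:, 0]
        pops = pmap.astype(str).to_dict()
    gm = gio.read_vcf(inputs["vcf"],
                      min_genotype_depth=cfg.get("qc", {}).get("min_genotype_depth", 10),
                      populations=pops)
    comm = gio.read_community(inputs["community"])
    env = gio.read_environment(inputs["environment"],
                               categorical=inputs.get("categorical", []))
    return gm, comm, env, None


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run all stages described by ``config``; returns a result bundle and
    writes TSV/JSON outputs when ``outdir`` (or ``config['outdir']``) is set."""
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "sgdc_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config, "seed": seed}
    log: dict = {"seed": seed}

    if "fixture" in config and "scenario" not in config and "inputs" not in config:
        table = (gio.load_carex_sites() if config["fixture"] == "packaged"
                 else gio.read_table(config["fixture"], kind="fixture"))
        rep = fixture_report(table)
        _write(rep.set_index("dataset"), outdir / "sgdc_results.tsv")
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        results["sgdc"] = rep
        return results

    gm, comm, env, truth = _load_inputs(config, seed)
    missing = set(gm.site_ids) - set(comm.site_ids)
    if missing:
        raise ValueError(f"community table missing genotyped sites: {sorted(missing)}")
    missing = set(gm.site_ids) - set(env.site_ids)
    if missing:
        raise ValueError(f"environment table missing genotyped sites: {sorted(missing)}")

    # QC
    qc_cfg = QCConfig(**config.get("qc", {}))
    gm, qc_report = apply_qc(gm, qc_cfg)
    gm = gm.orient_minor()
    _write(qc_report.to_frame(), outdir / "qc_report.tsv")
    log["qc"] = {k: v for k, v in vars(qc_cfg).items()}
    results["qc_report"] = qc_report

    # environment prescreen + scans
    scan_cfg = dict(config.get("scan", {}))
    env_r = prescreen_environment(env, scan_cfg.get("r_threshold", 0.7))
    vifs = vif_check(env_r)
    pca = PCAOutlierScan(k=scan_cfg.get("k", "auto"),
                         fdr_level=scan_cfg.get("fdr_level", 0.10),
                         random_state=seed).fit(gm)
    rda = RDAOutlierScan(n_perm=scan_cfg.get("n_perm", 999),
                         loading_multiplier=scan_cfg.get("loading_rule", {}).get("multiplier", 2.0),
                         loading_anchor=scan_cfg.get("loading_rule", {}).get("anchor", "quartile"),
                         axis_rule=scan_cfg.get("axis_rule", "min"),
                         random_state=seed).fit(gm, env_r)
    _write(pca.to_frame(), outdir / "pca_scan.tsv")
    _write(rda.to_frame(), outdir / "rda_scan.tsv")
    log["scan"] = {"k": pca.k_, "lambda": pca.lambda_,
                   "rda_variance_explained": rda.variance_explained_,
                   "rda_axes_retained": rda.n_retained_,
                   "vif": vifs.to_dict(), "environment_kept": env_r.variables}
    results.update(pca=pca, rda=rda, vif=vifs)

    # partition
    part = build_partition(gm.locus_ids, pca.outlier_loci(), rda.outlier_loci())
    _write(part.to_frame(), outdir / "partition.tsv")
    results["partition"] = part
    log["partition_sizes"] = part.sizes()

    # diversity
    div = diversity_table(gm, comm, part, min_genotyped=qc_cfg.min_genotyped_per_population)
    _write(div, outdir / "diversity.tsv")
    results["diversity"] = div
    bc = bray_curtis(comm)
    bc = bc.loc[div.index, div.index]
    _write(bc, outdir / "bray_curtis.tsv")
    dch = {}
    for name in ("ds1", "ds2", "ds3", "ds4", "ds5"):
        if part.mask(name).sum() == 0:
            continue
        D = cavalli_sforza_matrix(gm, part.mask(name),
                                  min_genotyped=qc_cfg.min_genotyped_per_population)
        dch[name.upper()] = D
        _write(D, outdir / f"dch_{name}.tsv")
    results["bray_curtis"] = bc
    results["dch"] = dch

    # SGDC tests
    sg = dict(config.get("sgdc", {}))
    tail = sg.get("tail", "one")
    mantel_perm = sg.get("mantel_permutations", 9999)
    n_subsets = sg.get("n_subsets", 999)
    rng = np.random.default_rng(seed)
    rows = []
    for name, D in dch.items():
        he = div[f"He_{name}"]
        for facet in ("richness", "evenness"):
            vals = div[facet]
            ok = ~(he.isna() | vals.isna())
            if ok.sum() >= 4 and he[ok].std() > 0 and vals[ok].std() > 0:
                res = alpha_sgdc(he[ok], vals[ok], tail=tail, dataset=name, facet=facet)
                rows.append({"dataset": name, "facet": facet, "test": "pearson_t",
                             "r": res.r, "n": res.n, "p": res.p})
        res = mantel_test(D, bc.loc[D.index, D.index], n_perm=mantel_perm,
                          rng=rng, dataset=name)
        rows.append({"dataset": name, "facet": "beta", "test": "mantel",
                     "r": res.r, "n": res.n, "p": res.p})
    sgdc_df = pd.DataFrame(rows)
    _write(sgdc_df.set_index("dataset"), outdir / "sgdc_results.tsv")
    results["sgdc"] = sgdc_df

    # equal-size subset randomizations: outlier datasets vs neutral references
    rand_rows = []
    if sg.get("randomization", True):
        for outlier_name in ("ds4", "ds5"):
            k = int(part.mask(outlier_name).sum())
            if k == 0:
                continue
            he_out = div[f"He_{outlier_name.upper()}"]
            for ref_name in ("ds1", "ds2", "ds3"):
                if part.mask(ref_name).sum() < k:
                    continue
                for facet in ("richness", "evenness"):
                    vals = div[facet]
                    ok = ~(he_out.isna() | vals.isna())
                    if ok.sum() < 4 or he_out[ok].std() == 0:
                        continue
                    obs = float(np.corrcoef(he_out[ok], vals[ok])[0, 1])
                    rr = subset_randomization(
                        gm, part.mask(ref_name), k, facet_values=vals[ok].values,
                        observed_r=obs, n_subsets=n_subsets,
                        seed=rng.integers(2 ** 31), tail="lower",
                        min_genotyped=qc_cfg.min_genotyped_per_population,
                        dataset=outlier_name.upper(), facet=facet)
                    rand_rows.append({"dataset": outlier_name.upper(), "reference": ref_name.upper(),
                                      "facet": facet, "observed_r": rr.observed_r,
                                      "subset_size": rr.subset_size, "p": rr.p, "tail": rr.tail})
    if rand_rows:
        _write(pd.DataFrame(rand_rows).set_index("dataset"), outdir / "randomization.tsv")
        results["randomization"] = pd.DataFrame(rand_rows)

    if truth is not None:
        truth.to_csv(outdir / "truth_labels.tsv", sep="\t")
    (outdir / "run_log.json").write_text(json.dumps(_jsonable(log), indent=2, sort_keys=True))
    results["log"] = log
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
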