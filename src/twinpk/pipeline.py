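"""End-to-end orchestration: simulate -> NCA -> occasion means ->
repeatability -> twin models -> multivariate decomposition -> covariates.

Every stage writes a tidy CSV/JSON artifact; a manifest records the
configuration, the seed and a content hash of every output so a run can
be reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig, TRAITS
from .simulate import simulate_study, SimulatedStudy
from .nca import nca_table
from .repeatability import repeatability_table
from .univariate import fit_unstructured, fit_variance_model, model_comparison
from .multivariate import fit_multivariate, correlation_decomposition
from .covariates import covariate_regression, genotype_contrast


class PipelineError(RuntimeError):
    pass


def build_trait_table(pk_results: pd.DataFrame, endogenous: pd.DataFrame,
                      subjects: pd.DataFrame) -> pd.DataFrame:
    """Subject-level table of occasion-mean phenotypes plus covariates.

    The four trait columns are the arithmetic means over occasions of
    the parent AUC_inf, metabolite AUC_inf, and the two endogenous
    biomarker measurements.  Occasion counts are recorded per trait;
    subjects missing a trait entirely get a missing value.
    """
    out = subjects.copy().set_index("subject_id")
    pieces = {
        "midazolam_auc": pk_results.query("analyte == 'midazolam'")
        .groupby("subject_id")["auc_inf"],
        "ohmidazolam_auc": pk_results.query("analyte == '1-OH-midazolam'")
        .groupby("subject_id")["auc_inf"],
    }
    for trait in ("ohcholesterol", "ohcortisol"):
        sub = endogenous.query("trait == @trait")
        pieces[trait] = sub.groupby("subject_id")["value"]
    for trait, grp in pieces.items():
        out[trait] = grp.mean()
        out[f"{trait}_n_occ"] = grp.count().reindex(out.index).fillna(0).astype(int)
    missing = out[list(pieces)].isna().any(axis=1)
    if missing.any():
        print(f"build_trait_table: {int(missing.sum())} subjects missing >=1 trait")
    return out.reset_index()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: StudyConfig, seed: int | None = None,
                 outdir: str | Path = "twinpk_run",
                 models: tuple[str, ...] = ("ACE", "AE", "CE"),
                 study: SimulatedStudy | None = None) -> dict:
    """Run every stage on a simulated study and write all artifacts.

    Returns the manifest (also written as ``manifest.json``).  Pass an
    existing :class:`SimulatedStudy` to skip the simulation stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    stages: list[str] = []
    report: list[str] = []

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        stages.append(name)
        return result

    if study is None:
        study = _stage("simulate", lambda: simulate_study(config, seed))
    _write_csv(study.subjects, outdir / "subjects.csv")
    _write_csv(study.concentrations, outdir / "concentrations.csv")
    _write_csv(study.endogenous, outdir / "endogenous.csv")
    (outdir / "truth.json").write_text(json.dumps(study.truth, indent=1))

    weights = study.subjects.set_index("subject_id")["weight"]
    pk = _stage("nca", lambda: nca_table(study.concentrations, config.dose_ug, weights))
    _write_csv(pk, outdir / "pk_results.csv")

    traits_tbl = _stage("trait_table",
                        lambda: build_trait_table(pk, study.endogenous, study.subjects))
    _write_csv(traits_tbl, outdir / "trait_table.csv")

    if config.n_occasions >= 2:
        long = pd.concat([
            pk.query("analyte == 'midazolam'")
            .assign(trait="midazolam_auc")[["subject_id", "trait", "auc_inf"]]
            .rename(columns={"auc_inf": "value"}),
            pk.query("analyte == '1-OH-midazolam'")
            .assign(trait="ohmidazolam_auc")[["subject_id", "trait", "auc_inf"]]
            .rename(columns={"auc_inf": "value"}),
            study.endogenous[["subject_id", "trait", "value"]],
        ], ignore_index=True)
        rep = _stage("repeatability", lambda: repeatability_table(long))
        _write_csv(rep, outdir / "repeatability.csv")
        report.append("Genetic component (rGC) per trait:")
        for _, r in rep.iterrows():
            report.append(f"  {r['trait']:<18s} rGC = {r['r_gc']:.3f}")
    else:
        report.append("repeatability stage skipped: single occasion per subject")

    fits_rows = []
    truth_h2 = dict(zip(study.truth["traits"], study.truth["h2"]))
    truth_c2 = dict(zip(study.truth["traits"], study.truth["c2"]))
    report.append("\nUnivariate twin models (log scale, age+sex means):")
    fits_by_trait = {}
    for trait in TRAITS:
        def _fit_all(trait=trait):
            out = {"unstructured": fit_unstructured(traits_tbl, trait)}
            for m in models:
                out[m] = fit_variance_model(traits_tbl, trait, model=m)
            return out
        fits = _stage(f"twinfit:{trait}", _fit_all)
        fits_by_trait[trait] = fits
        uns = fits["unstructured"]
        ace = fits.get("ACE")
        report.append(
            f"  {trait:<18s} r_mz={uns.r_mz:.2f} r_dz={uns.r_dz:.2f}  "
            f"H2={ace.h2:.2f} (truth {truth_h2.get(trait, float('nan')):.2f})  "
            f"C2={ace.c2_prop:.2f} (truth {truth_c2.get(trait, float('nan')):.2f})")
        for name, f in fits.items():
            fits_rows.append({
                "trait": trait, "model": name, "loglik": f.loglik,
                "df": f.n_params, "AIC": f.aic, "BIC": f.bic,
                "h2": f.h2, "c2_prop": f.c2_prop, "e2_prop": f.e2_prop,
                "r_mz": f.r_mz, "r_dz": f.r_dz,
                "h2_se": f.se.get("h2"), "c2_se": f.se.get("c2_prop"),
                "converged": f.converged,
            })
    fits_df = pd.DataFrame(fits_rows)
    _write_csv(fits_df, outdir / "twin_fits.csv")
    (outdir / "twin_fits.json").write_text(
        fits_df.to_json(orient="records", indent=1))

    mv = _stage("mvtwin", lambda: fit_multivariate(traits_tbl, TRAITS, model="ACE"))
    dec = correlation_decomposition(mv)
    (outdir / "mv_fit.json").write_text(json.dumps({
        "model": mv.model, "traits": list(mv.traits),
        "A": mv.A.tolist(), "C": mv.C.tolist(), "E": mv.E.tolist(),
        "loglik": mv.loglik, "n_params": mv.n_params,
        "converged": mv.converged,
    }, indent=1))
    _write_csv(dec.tidy(), outdir / "correlations.csv")
    report.append("\nMultivariate ACE genetic correlations (r_g):")
    for _, row in dec.tidy().iterrows():
        report.append(f"  {row['trait_j']} ~ {row['trait_k']}: "
                      f"r_g={row['r_g']:.2f} r_e={row['r_e']:.2f} "
                      f"r_ph={row['r_ph']:.2f}")

    cov_frames, contrasts = [], []
    for trait in TRAITS:
        cov_frames.append(_stage(
            f"covars:{trait}",
            lambda trait=trait: covariate_regression(traits_tbl, trait, log_scale=True)))
    try:
        contrasts.append(genotype_contrast(traits_tbl, "midazolam_auc", "cyp3a4_22").__dict__)
        contrasts.append(genotype_contrast(traits_tbl, "ohcholesterol", "cyp3a5_1").__dict__)
    except Exception as exc:  # a tiny cohort may lack carriers entirely
        report.append(f"\ngenotype contrasts skipped: {exc}")
    _write_csv(pd.concat(cov_frames, ignore_index=True), outdir / "covariates.csv")
    if contrasts:
        _write_csv(pd.DataFrame(contrasts), outdir / "contrasts.csv")

    (outdir / "report.txt").write_text("\n".join(report) + "\n")

    manifest = {
        "package": "twinpk", "version": __version__, "seed": seed,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": config.to_dict(),
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
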