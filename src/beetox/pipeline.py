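"""End-to-end orchestration: generate or load data, DE per contrast, overlap
and contrast statistics, resampling diagnostics, survival and dose accounting.

A run writes every output table under an output directory and records each
file's SHA-256 in a manifest, so identical configurations and seeds yield
identical manifests.  The single global seed expands deterministically into
per-stage seeds (stage k uses ``SeedSequence([seed, k])``-style derivation
inside each module), so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .config import CONTROL, DESettings, SynthConfig
from .contrasts import top_k_amplitude, variance_contrast, welch_t  # noqa: F401
from .de import de_pipeline, filter_low_counts, significant_genes, size_factors, vst_transform
from .overlap import GeneSetCollection, euler_regions, overlap_test
from .resampling import ConfoundConfig, SubsampleConfig, balanced_subsample_de, colony_confound_resample
from .simulate import (
    DEFAULT_HAZARD_RATIOS,
    DEFAULT_INTAKE_SLOPES,
    EXPERIMENT_DAYS,
    generate_counts,
    generate_intake,
    generate_survival,
)
from .survival import SolutionSpec, cox_ph, cumulative_dose, intake_ols, ppb_concentration, survival_proportion

CHRONIC_SOLUTION = SolutionSpec(pesticide_mass_conc=5.0)
ACUTE_SOLUTION = SolutionSpec(pesticide_mass_conc=25.0)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (synthetic mode or file inputs)."""

    outdir: str = "beetox_run"
    seed: int = 0
    synth: SynthConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    survival_path: str | None = None
    intake_path: str | None = None
    de: DESettings = field(default_factory=DESettings)
    overlap_iterations: int = 10000
    subsample: SubsampleConfig = field(default_factory=SubsampleConfig)
    confound: ConfoundConfig = field(default_factory=ConfoundConfig)
    run_resampling: bool = True

    def validate(self) -> None:
        synth_mode = self.synth is not None
        file_mode = self.counts_path is not None and self.metadata_path is not None
        if synth_mode == file_mode:
            raise ValueError("provide exactly one of: a SynthConfig, or counts+metadata paths")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    stage = "setup"

    def emit(writer, obj, relpath: str) -> Path:
        path = out / relpath
        writer(obj, path)
        files.append(relpath)
        return path

    try:
        # ---- data ---------------------------------------------------
        stage = "generate"
        if config.synth is not None:
            synth = dataclasses.replace(config.synth, seed=config.seed)
            counts, meta, truth = generate_counts(synth)
            survival_records = generate_survival(synth)
            intake_records = generate_intake(synth)
            emit(io.write_counts, counts, "counts.tsv")
            emit(io.write_metadata, meta, "metadata.csv")
            path = out / "truth.tsv"
            io.write_truth(truth.lfc, truth.category, path)
            files.append("truth.tsv")
            emit(io.write_survival, survival_records, "survival.csv")
            emit(io.write_intake, intake_records, "intake.csv")
        else:
            counts = io.read_counts(config.counts_path)
            meta = io.read_metadata(config.metadata_path)
            survival_records = io.read_survival(config.survival_path) if config.survival_path else None
            intake_records = io.read_intake(config.intake_path) if config.intake_path else None

        treatments = [t for t in meta["treatment"].unique() if t != CONTROL]

        # ---- differential expression -------------------------------
        stage = "de"
        filtered = filter_low_counts(counts, config.de)
        de_tables = de_pipeline(counts, meta, config.de, contrasts=treatments)
        de_counts = {}
        for contrast, table in de_tables.items():
            emit(io.write_de_table, table, f"de_{contrast}.tsv")
            emit(io.write_gene_list, significant_genes(table), f"genes_{contrast}.txt")
            de_counts[contrast] = int(table["significant"].sum())

        # ---- overlaps ----------------------------------------------
        stage = "overlap"
        pool_size = len(filtered)
        overlap_rows = []
        euler_rows = []
        for scheme in ("acute", "chronic"):
            names = [t for t in treatments if t.endswith("_" + scheme)]
            sets = {t: frozenset(significant_genes(de_tables[t])) for t in names}
            if len(sets) < 2 or any(len(s) == 0 for s in sets.values()):
                continue
            coll = GeneSetCollection(pool_size=pool_size, sets=sets)
            res = overlap_test(coll, n_iterations=config.overlap_iterations, seed=config.seed)
            overlap_rows.append(
                {
                    "comparison": f"all_{scheme}",
                    "observed": res.observed,
                    "expected": res.expected,
                    "expected_analytic": res.expected_analytic,
                    "expected_se": res.expected_se,
                    "fold_enrichment": res.fold_enrichment,
                    "p_value": res.p_value,
                    "n_iterations": res.n_iterations,
                }
            )
            for sig, count in sorted(euler_regions(coll).items()):
                euler_rows.append({"comparison": f"all_{scheme}", "region": sig, "count": count})
        emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(overlap_rows), "overlap.csv")
        emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(euler_rows), "euler_regions.csv")

        # ---- scheme contrasts --------------------------------------
        stage = "contrast"
        contrast_rows = []
        factors = size_factors(filtered)
        vst = vst_transform(filtered, factors, config.de)
        for compound in sorted({t.rsplit("_", 1)[0] for t in treatments}):
            acute_label, chronic_label = f"{compound}_acute", f"{compound}_chronic"
            if acute_label not in de_tables or chronic_label not in de_tables:
                continue
            try:
                amp = top_k_amplitude(de_tables[acute_label], de_tables[chronic_label], k=20)
                contrast_rows.append(
                    {
                        "statistic": f"amplitude_ratio[{compound}]",
                        "value": amp.ratio,
                        "df": amp.df,
                        "p": amp.p,
                        "method": "welch_t_top20_abs_log2fc",
                    }
                )
            except ValueError:
                pass
        de_any = pd.Series(False, index=vst.index)
        for table in de_tables.values():
            de_any |= table["significant"].reindex(vst.index, fill_value=False)
        if de_any.any() and (~de_any).any():
            try:
                vc = variance_contrast(vst, meta, de_any)
                contrast_rows.append(
                    {
                        "statistic": "variance_inflation_coefficient",
                        "value": vc.coefficient,
                        "df": vc.df,
                        "p": vc.p,
                        "method": "paired_log_sd_difference",
                    }
                )
            except ValueError:
                pass
        emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(contrast_rows), "contrast_stats.csv")

        # ---- resampling --------------------------------------------
        stage = "resample"
        if config.run_resampling:
            acute_labels = [t for t in treatments if t.endswith("_acute")]
            sub_cfg = dataclasses.replace(config.subsample, seed=config.seed)
            summaries = balanced_subsample_de(counts, meta, acute_labels, sub_cfg, config.de)
            rows = []
            for chronic, summary in summaries.items():
                for i, c in enumerate(summary.de_counts):
                    rows.append({"contrast": chronic, "iteration": i + 1, "de_count": int(c)})
            emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(rows), "subsample_de_counts.csv")
            sub_json = {
                chronic: {
                    "median": s.median,
                    "skewness": None if pd.isna(s.skewness) else s.skewness,
                    "permutation_p": s.p_values,
                }
                for chronic, s in summaries.items()
            }
            (out / "subsample_summary.json").write_text(json.dumps(sub_json, indent=2, sort_keys=True))
            files.append("subsample_summary.json")

            conf_cfg = dataclasses.replace(config.confound, seed=config.seed)
            focal = "clothianidin_chronic" if "clothianidin_chronic" in treatments else treatments[0]
            matched, mismatched, ks = colony_confound_resample(counts, meta, focal, conf_cfg, config.de)
            rows = [
                {"mode": "matched", "iteration": i + 1, "de_count": int(c)}
                for i, c in enumerate(matched.de_counts)
            ] + [
                {"mode": "mismatched", "iteration": i + 1, "de_count": int(c)}
                for i, c in enumerate(mismatched.de_counts)
            ]
            emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(rows), "confound_de_counts.csv")
            conf_json = {
                "treatment": focal,
                "matched_median": matched.median,
                "mismatched_median": mismatched.median,
                "matched_skewness": None if pd.isna(matched.skewness) else matched.skewness,
                "mismatched_skewness": None if pd.isna(mismatched.skewness) else mismatched.skewness,
                "ks_D": ks[0],
                "ks_p": ks[1],
            }
            (out / "confound_summary.json").write_text(json.dumps(conf_json, indent=2, sort_keys=True))
            files.append("confound_summary.json")

        # ---- survival and dose -------------------------------------
        stage = "survival"
        if survival_records is not None:
            rows = []
            for treatment in treatments:
                mortality = survival_proportion(survival_records, treatment, EXPERIMENT_DAYS)
                row = {"treatment": treatment, "mortality_at_day14": mortality}
                try:
                    res = cox_ph(survival_records, treatment)
                    row.update(
                        beta=res.beta, se=res.se, hazard_ratio=res.hazard_ratio,
                        z=res.z, p=res.p, score_chi2=res.score_chi2,
                        score_p=res.score_p, n=res.n, n_events=res.n_events,
                        method="cox_breslow",
                    )
                except ValueError as err:
                    # e.g. no event in the analysis window at small n
                    row.update(method=f"cox_breslow_skipped: {err}")
                rows.append(row)
            emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(rows), "survival_stats.csv")
        if intake_records is not None:
            chronic_labels = [t for t in treatments if t.endswith("_chronic")]
            rows = []
            if chronic_labels:
                table = intake_ols(intake_records, treatments=chronic_labels)
                table.insert(0, "model", "chronic_all_days")
                rows.append(table)
            acute_labels = [t for t in treatments if t.endswith("_acute")]
            if acute_labels:
                table = intake_ols(intake_records, treatments=acute_labels, acute_window=True)
                table.insert(0, "model", "acute_days_12_14")
                rows.append(table)
            if rows:
                emit(
                    lambda df, p: io._write(df, p, ",", False),
                    pd.concat(rows, ignore_index=True),
                    "intake_ols.csv",
                )
            dose_rows = []
            for treatment in treatments:
                solution = ACUTE_SOLUTION if treatment.endswith("_acute") else CHRONIC_SOLUTION
                sub = intake_records.loc[intake_records["treatment"] == treatment]
                if treatment.endswith("_acute"):
                    sub = sub.loc[sub["day"] > EXPERIMENT_DAYS - 2]
                else:
                    sub = sub.loc[sub["day"] > 2]  # chronic exposure starts after day 2
                _, median_dose = cumulative_dose(sub, solution)
                dose_rows.append(
                    {
                        "treatment": treatment,
                        "solution_ppb": ppb_concentration(solution),
                        "median_dose_ug_per_bee": median_dose,
                    }
                )
            emit(lambda df, p: io._write(df, p, ",", False), pd.DataFrame(dose_rows), "dose.csv")
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "seed": config.seed,
        "outdir": str(out),
        "de_counts": de_counts,
        "files": {f: _sha256(out / f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_report(manifest: dict, path=None) -> str:
    """Render a plain-markdown summary of a completed run."""
    out = Path(manifest["outdir"])
    lines = ["# beetox run report", ""]
    lines.append(f"Seed: {manifest['seed']}")
    lines.append("")
    lines.append("## Differentially expressed genes per contrast (FDR 0.05)")
    lines.append("")
    lines.append("| contrast | DE genes |")
    lines.append("|---|---|")
    for contrast, n in sorted(manifest["de_counts"].items()):
        lines.append(f"| {contrast} | {n} |")
    for name, title in [
        ("overlap.csv", "Overlap statistics"),
        ("contrast_stats.csv", "Scheme contrasts"),
        ("survival_stats.csv", "Survival (Cox vs control)"),
        ("dose.csv", "Dose accounting"),
    ]:
        lines.append("")
        lines.append(f"## {title}")
        lines.append("")
        f = out / name
        if name in manifest["files"] and f.exists():
            df = pd.read_csv(f)
            if df.empty:
                lines.append("(no rows)")
            else:
                lines.append(df.to_markdown(index=False))
        else:
            lines.append("(section absent)")
    text = "\n".join(lines) + "\n"
    if path is None:
        path = out / "report.md"
    Path(path).write_text(text)
    return text
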