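"""End-to-end study orchestration: simulate -> detect -> extract ->
morphometry -> compare.

`run_study` mirrors a two-group specimen study: a cohort of sham and
treated specimens is synthesized (two cartilage sites per specimen -
medial- and lateral-plateau-like parameterizations - plus one
trabecular volume), every scan is processed to the four acoustic
parameters, every volume to the trabecular panel, and each parameter is
compared between groups with the exact Mann-Whitney U test.

The shipped default configuration applies degradation-like effects to
the cartilage truth of the treated group (rougher surface, reduced
surface reflectivity at the first site, thinner cartilage) and no
effect to bone, so the comparison table reproduces the qualitative
pattern of early estrogen-deficiency studies: cartilage parameters
significant, bone parameters not.  Effect sizes are synthetic defaults,
not estimates of any measured cohort.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cartiqus.acoustic import compute_acoustic_params
from cartiqus.morphometry import compute_morphometry
from cartiqus.rf_processing import DetectionConfig, detect_echoes
from cartiqus.stats import summarize_groups
from cartiqus.synthetic import (
    CartilageEffects,
    CartilagePhantomSpec,
    CohortSpec,
    generate_cohort,
)

BONE_PARAMETERS = ("BV_TV", "Tb_N_per_mm", "Tb_Th_mm", "Tb_Sp_mm", "Conn_D_per_mm3", "SMI")
CARTILAGE_PARAMETERS = ("URI_um", "RC1_pct", "RC2_pct", "h_mm")


@dataclass
class StudyConfig:
    """Everything needed to rerun a study end to end."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    make_figures: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    acoustic_table: pd.DataFrame
    morphometry_table: pd.DataFrame
    parameter_table: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: pd.DataFrame
    meta: dict


def default_study_config(seed: int = 0, out_dir: str | None = None) -> StudyConfig:
    """The shipped demo study: n = 7 + 7, two cartilage sites, cartilage
    effects on, bone effects off."""
    cohort = CohortSpec(
        n_per_group=7,
        cartilage={
            "mtp": CartilagePhantomSpec(thickness_mean_mm=0.25),
            "ltp": CartilagePhantomSpec(thickness_mean_mm=0.30),
        },
        effects={
            "mtp": CartilageEffects(roughness=3.0, r_surface=0.6, thickness=0.75),
            "ltp": CartilageEffects(roughness=2.5, r_surface=1.0, thickness=0.75),
        },
        seed=seed,
    )
    return StudyConfig(cohort=cohort, seed=seed, out_dir=out_dir)


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the full study described by *cfg*; optionally write the
    report bundle (CSV tables, run manifest, optional figures)."""
    cohort_spec = replace(cfg.cohort, seed=cfg.seed)
    cohort = generate_cohort(cohort_spec)

    acoustic_rows = []
    morpho_rows = []
    wide_rows = []
    n_excluded_lines = 0
    for spec_data in cohort.specimens:
        wide: dict = {"specimen_id": spec_data.specimen_id, "group": spec_data.group}
        for site, scan in spec_data.scans.items():
            try:
                feats = detect_echoes(scan, cohort.reference, cfg.detection)
                params = compute_acoustic_params(feats, c_cartilage=scan.c_cartilage)
            except ValueError as err:
                raise RuntimeError(
                    f"[rf_processing/acoustic] specimen {spec_data.specimen_id} "
                    f"site {site}: {err}"
                ) from err
            n_excluded_lines += feats.metadata["n_excluded_surface"]
            row = {"specimen_id": spec_data.specimen_id, "group": spec_data.group, "site": site}
            row.update(params.to_dict())
            acoustic_rows.append(row)
            for key in CARTILAGE_PARAMETERS:
                wide[f"{site}_{key}"] = row[key]
        try:
            morpho = compute_morphometry(spec_data.volume)
        except ValueError as err:
            raise RuntimeError(
                f"[bone_morphometry] specimen {spec_data.specimen_id}: {err}"
            ) from err
        mrow = {"specimen_id": spec_data.specimen_id, "group": spec_data.group}
        mrow.update(morpho.to_dict())
        morpho_rows.append(mrow)
        wide.update(morpho.to_dict())
        wide_rows.append(wide)

    acoustic_table = pd.DataFrame(acoustic_rows)
    morpho_table = pd.DataFrame(morpho_rows)
    parameter_table = pd.DataFrame(wide_rows)
    comparisons = summarize_groups(
        parameter_table.drop(columns=["specimen_id"]),
        group_order=cohort_spec.group_names,
        alpha=cfg.alpha,
    )
    from cartiqus import __version__

    meta = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "alpha": cfg.alpha,
        "n_per_group": cohort_spec.n_per_group,
        "sites": list(cohort_spec.cartilage),
        "n_excluded_lines": int(n_excluded_lines),
    }
    report = StudyReport(
        acoustic_table=acoustic_table,
        morphometry_table=morpho_table,
        parameter_table=parameter_table,
        comparisons=comparisons,
        manifest=cohort.manifest,
        meta=meta,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir), cfg)
    return report


def _write_report(report: StudyReport, out: Path, cfg: StudyConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    for name, table in [
        ("acoustic_params.csv", report.acoustic_table),
        ("morphometry.csv", report.morphometry_table),
        ("parameters_wide.csv", report.parameter_table),
        ("comparisons.csv", report.comparisons),
        ("manifest.csv", report.manifest),
    ]:
        t = table.copy()
        for k, v in stamp.items():
            t[k] = v
        t.to_csv(out / name, index=False)
    (out / "run_manifest.json").write_text(json.dumps(report.meta, indent=2))
    if cfg.make_figures:
        plot_comparisons(report, out / "comparisons.png")


def plot_comparisons(report: StudyReport, path) -> None:
    """Bar chart of group mean +/- SD per parameter, starred when the
    exact test is significant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmp_ = report.comparisons
    n = len(cmp_)
    ncols = 4
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    for ax, (_, row) in zip(axes.ravel(), cmp_.iterrows()):
        ax.bar([0, 1], [row["mean1"], row["mean2"]], yerr=[row["sd1"], row["sd2"]],
               color=["0.7", "0.4"], capsize=4)
        ax.set_xticks([0, 1])
        ax.set_xticklabels(cmp_.attrs.get("groups", ["g1", "g2"]))
        title = row["parameter"]
        if row["significant"]:
            title += " *"
        ax.set_title(f"{title}\np={row['p_value']:.3g}", fontsize=9)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
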