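"""End-to-end per-sample and per-platform comparison runs.

Takes a sample manifest (TSV: sample, platform, filtered/unfiltered
bedgraph paths, optional design and VCF paths), computes per-sample
summaries and evenness scores, fits the per-platform coverage model,
predicts the low-coverage curve, and writes everything as TSV (plus
optional plots — numbers never live only in a figure).

Stages are content-addressed: each stage writes a sidecar recording the
SHA-256 of its inputs and options, and an unchanged rerun skips the
computation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import evenness, model
from .intervals import IntervalSet, annotate_gc, read_bed

log = logging.getLogger("covbias")

MANIFEST_COLUMNS = ["sample", "platform", "bedgraph", "bedgraph_unfiltered"]
OPTIONAL_COLUMNS = ["design", "vcf"]


@dataclass
class RunOptions:
    depth_grid: tuple[float, ...] = tuple(float(d) for d in range(20, 201, 20))
    depth_threshold: float = 10.0
    low_cutoff: float = 0.1
    min_mean_depth: float = 10.0
    n_rep: int = 100
    seed: int = 0
    plots: bool = False


def read_manifest(path: str) -> pd.DataFrame:
    """Load and validate the sample manifest; raises with an itemized list
    of schema problems before any computation starts."""
    df = pd.read_csv(path, sep="\t")
    problems = []
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if not problems:
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            problems.append(f"duplicate sample ids: {dups}")
        for col in ["bedgraph", "bedgraph_unfiltered", "design", "vcf"]:
            if col not in df.columns:
                continue
            for _, row in df.iterrows():
                p = row[col]
                if isinstance(p, str) and p and not Path(p).exists():
                    problems.append(f"sample {row['sample']}: {col} file not found: {p}")
    if problems:
        raise ValueError("manifest errors:\n  - " + "\n  - ".join(problems))
    return df


def _hash_inputs(paths: list[str], options: dict) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.encode())
        h.update(Path(p).read_bytes())
    h.update(json.dumps(options, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_fresh(outdir: Path, name: str, digest: str, outputs: list[Path]) -> bool:
    """True when the stage must run (missing outputs or changed inputs)."""
    sidecar = outdir / f".{name}.stage.json"
    if sidecar.exists() and all(o.exists() for o in outputs):
        recorded = json.loads(sidecar.read_text()).get("digest")
        if recorded == digest:
            log.info("stage %s: inputs unchanged, skipping", name)
            return False
    return True


def _stage_done(outdir: Path, name: str, digest: str, t0: float, n_records: int) -> None:
    sidecar = outdir / f".{name}.stage.json"
    sidecar.write_text(
        json.dumps({"digest": digest, "seconds": round(time.time() - t0, 3), "records": n_records})
    )
    log.info("stage %s: done in %.2fs (%d records)", name, time.time() - t0, n_records)


def run_platform_comparison(
    manifest: pd.DataFrame | str,
    cds_path: str,
    outdir: str,
    options: RunOptions | None = None,
    genome_fasta: str | None = None,
) -> Path:
    """Run the full comparison over a manifest; returns the report directory.

    Per sample: interval summaries and OE/BIE/WIE (written to
    ``sample_summaries/`` and ``evenness.tsv``). Per platform (needs >= 2
    samples): model fit, low-coverage prediction curve, mean pairwise
    correlation and the intersection-to-union reproducibility ratio.
    """
    options = options or RunOptions()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "sample_summaries").mkdir(exist_ok=True)
    if isinstance(manifest, str):
        manifest_df = read_manifest(manifest)
    else:
        manifest_df = manifest

    log.info("config: %s", options)
    cds = read_bed(cds_path).merge()
    gc = annotate_gc(cds, genome_fasta) if genome_fasta else None

    evenness_rows = []
    norm_by_platform: dict[str, dict[str, np.ndarray]] = {}
    summaries_by_sample: dict[str, pd.DataFrame] = {}
    lengths = np.array([iv.length for iv in cds])

    for row in manifest_df.itertuples():
        t0 = time.time()
        inputs = [cds_path, row.bedgraph, row.bedgraph_unfiltered]
        if _has(row, "design"):
            inputs.append(row.design)
        digest = _hash_inputs(
            inputs, {"min_mean_depth": options.min_mean_depth, "genome": genome_fasta}
        )
        summary_path = out / "sample_summaries" / f"{row.sample}.tsv"
        ev_path = out / "sample_summaries" / f"{row.sample}.evenness.json"
        name = f"sample_{row.sample}"
        if _stage_fresh(out, name, digest, [summary_path, ev_path]):
            design = read_bed(row.design).merge() if _has(row, "design") else None
            filt = cov.read_bedgraph(row.bedgraph, cds, sample_id=row.sample)
            unfilt = cov.read_bedgraph(row.bedgraph_unfiltered, cds, sample_id=row.sample)
            summary = cov.summarize_intervals(filt, unfilt, cds, gc=gc, design=design)
            summary.to_csv(summary_path, sep="\t", index=False)

            oe = evenness.oe_score(evenness.base_profile(filt))
            bie = evenness.bie_score(
                evenness.interval_profile(summary["norm_mean"].to_numpy())
            )
            try:
                wie = evenness.wie_score(
                    evenness.within_interval_profile(
                        filt, cds, min_mean_depth=options.min_mean_depth
                    )
                )
            except ValueError:
                wie = float("nan")
            ev_path.write_text(
                json.dumps(
                    {"mean_cds_depth": filt.mean_depth(), "oe": oe, "bie": bie, "wie": wie}
                )
            )
            _stage_done(out, name, digest, t0, len(summary))
        else:
            summary = pd.read_csv(summary_path, sep="\t")
        scores = json.loads(ev_path.read_text())
        summaries_by_sample[row.sample] = summary
        evenness_rows.append({"sample": row.sample, "platform": row.platform, **scores})
        norm_by_platform.setdefault(row.platform, {})[row.sample] = summary[
            "norm_mean"
        ].to_numpy()

    pd.DataFrame(evenness_rows).to_csv(out / "evenness.tsv", sep="\t", index=False)

    pred_rows = []
    repro_rows = []
    for platform, cols in norm_by_platform.items():
        if len(cols) < 2:
            log.warning("platform %s has < 2 samples; model fit skipped", platform)
            continue
        mat = np.column_stack(list(cols.values()))
        shape100 = None
        fitted = model.fit_model(mat, lengths, shape_profile=shape100)
        pred = model.predict_low_coverage(
            fitted,
            options.depth_grid,
            threshold=options.depth_threshold,
            n_rep=options.n_rep,
            seed=options.seed,
        )
        for d, b, se in zip(pred.mean_depth_grid, pred.bases_below, pred.se):
            pred_rows.append(
                {"platform": platform, "mean_depth": d, "bases_below": b, "se": se}
            )
        rep = model.reproducibility_report(mat, cds, cutoff=options.low_cutoff)
        repro_rows.append(
            {
                "platform": platform,
                "mean_pairwise_r": rep.mean_pairwise_r,
                "r_ratio": rep.r_ratio,
                "cutoff": rep.cutoff,
                "n_samples": rep.n_samples,
            }
        )
    if pred_rows:
        pd.DataFrame(pred_rows).to_csv(out / "low_coverage_prediction.tsv", sep="\t", index=False)
    if repro_rows:
        pd.DataFrame(repro_rows).to_csv(out / "reproducibility.tsv", sep="\t", index=False)

    if options.plots and pred_rows:
        _plot_curves(pd.DataFrame(pred_rows), out / "low_coverage_prediction.png")
        _plot_evenness(pd.DataFrame(evenness_rows), out / "evenness.png")
    return out


def _has(row, attr: str) -> bool:
    val = getattr(row, attr, None)
    return isinstance(val, str) and bool(val)


def _plot_curves(pred: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for platform, grp in pred.groupby("platform"):
        ax.plot(grp["mean_depth"], grp["bases_below"] / 1e3, marker="o", label=platform)
    ax.set_xlabel("mean CDS depth")
    ax.set_ylabel("kbp below threshold")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_evenness(ev: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3), sharey=True)
    for ax, metric in zip(axes, ["oe", "bie", "wie"]):
        for k, (platform, grp) in enumerate(ev.groupby("platform")):
            ax.scatter([k] * len(grp), grp[metric], s=12)
        ax.set_title(metric.upper())
        ax.set_xticks(range(ev["platform"].nunique()))
        ax.set_xticklabels(sorted(ev["platform"].unique()), rotation=45)
    axes[0].set_ylabel("score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
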