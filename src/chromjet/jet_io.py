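"""Output writers, cross-chromosome combination and the command-line tool.

Every output folder receives a machine-readable ``parameters.json`` with the
full configuration and package version, sufficient to re-run the call.  One
sub-folder is produced per (alpha, saliency percentile) combination, each with
a summary table (one row per jet), an expanded table (one row per ridge
position), a bedpe annotation loadable in contact-map browsers, and a
diagnostic image.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .config import preset_config
from .pipeline import JetResult, call_jets

logger = logging.getLogger("chromjet")


def write_tables(summary: pd.DataFrame, expanded: pd.DataFrame, outdir) -> tuple:
    """Write the summary and expanded CSVs (headers are written even when
    there are zero jets); the two tables join on ``unique_id``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spath = outdir / "jets_summary.csv"
    epath = outdir / "jets_expanded.csv"
    summary.to_csv(spath, index=False)
    expanded.to_csv(epath, index=False)
    return spath, epath


def write_bedpe(summary: pd.DataFrame, path, resolution: int) -> Path:
    """One bedpe record per jet: anchor1 is the origin bin (the jet end
    nearest the diagonal, projected onto it), anchor2 the far bin of the tip
    contact; 0-based half-open, score = saliency."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tstrand1\tstrand2\n")
        for _, row in summary.iterrows():
            if "origin_bin" in row.index:
                a1 = int(row["origin_bin"]) * resolution
                a2 = int(row["tip_bin"]) * resolution
            else:
                a1 = int(row["start_bp"])
                a2 = int(row["end_bp"])
            fh.write(f"{row['chromosome']}\t{a1}\t{a1 + resolution}\t"
                     f"{row['chromosome']}\t{a2}\t{a2 + resolution}\t"
                     f"{row['unique_id']}\t{row['saliency']:.6g}\t.\t.\n")
    return path


def write_diagnostic(result: JetResult, path) -> Path:
    """Strip image with called ridges overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.imshow(result.strip.pixels, cmap="Reds", aspect="auto", interpolation="nearest")
    for r in result.ridges:
        ax.plot(r.points[:, 1], r.points[:, 0], lw=1.0, color="cyan")
    ax.set_xlabel("bin")
    ax.set_ylabel("strip row")
    ax.set_title(f"{result.chromosome}: {len(result.ridges)} candidate jets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_scale_debug(strip_pixels, ridges, scale: float, outdir) -> None:
    """Per-scale debug output: the strip with raw traces overlaid (PNG) and a
    coordinates/angle/width table (CSV)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"scale_{scale:.3f}"
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.imshow(strip_pixels, cmap="Reds", aspect="auto", interpolation="nearest")
    for r in ridges:
        ax.plot(r.points[:, 1], r.points[:, 0], lw=0.8, color="cyan")
    ax.set_title(f"s = {scale:.3f}: {len(ridges)} raw traces")
    fig.tight_layout()
    fig.savefig(outdir / f"{tag}_overlay.png", dpi=100)
    plt.close(fig)
    rows = []
    for k, r in enumerate(ridges):
        for i in range(r.n_points):
            rows.append({"ridge": k, "y": r.points[i, 0], "x": r.points[i, 1],
                         "angle": r.angles[i], "width": r.widths[i],
                         "response": r.responses[i]})
    pd.DataFrame(rows, columns=["ridge", "y", "x", "angle", "width",
                                "response"]).to_csv(outdir / f"{tag}_table.csv",
                                                    index=False)


def write_run(result: JetResult, outdir) -> Path:
    """Write all outputs for one chromosome run, one sub-folder per
    (alpha, saliency_thresh) combination."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    provenance = {"version": __version__, "chromosome": result.chromosome,
                  "stage_counts": result.stage_counts, "parameters": cfg.to_dict()}
    (outdir / "parameters.json").write_text(json.dumps(provenance, indent=2, default=list))
    write_tables(result.summary, result.expanded, outdir)
    write_diagnostic(result, outdir / "diagnostic.png")
    for alpha in cfg.alpha:
        sub = outdir / f"results_saliency-{cfg.saliency_thresh:g}-p-{alpha:g}"
        sub.mkdir(exist_ok=True)
        sig_summary = result.significant(alpha, cfg.saliency_thresh)
        sig_expanded = result.expanded[result.expanded["unique_id"].isin(
            sig_summary["unique_id"])] if len(sig_summary) else result.expanded.iloc[0:0]
        write_tables(sig_summary, sig_expanded, sub)
        write_bedpe(sig_summary, sub / "jets.bedpe", cfg.resolution)
        (sub / "parameters.json").write_text(json.dumps(
            {**provenance, "alpha": alpha, "saliency_thresh": cfg.saliency_thresh},
            indent=2, default=list))
    return outdir


def combine_chromosomes(result_dirs) -> tuple:
    """Concatenate per-chromosome summary/expanded tables from runs with
    identical parameter sets; unique_ids are re-namespaced by chromosome.

    Raises on mismatched parameters or versions.
    """
    summaries, expandeds = [], []
    reference = None
    for d in result_dirs:
        d = Path(d)
        prov = json.loads((d / "parameters.json").read_text())
        check = {k: v for k, v in prov["parameters"].items() if k != "seed"}
        check["version"] = prov["version"]
        if reference is None:
            reference = check
        elif check != reference:
            diff = {k for k in check if check[k] != reference.get(k)}
            raise ValueError(f"parameter mismatch across runs in {d}: {sorted(diff)}")
        s = pd.read_csv(d / "jets_summary.csv")
        e = pd.read_csv(d / "jets_expanded.csv")
        chrom = prov["chromosome"]
        s["unique_id"] = [f"{chrom}:{u}" for u in s["unique_id"]]
        e["unique_id"] = [f"{chrom}:{u}" for u in e["unique_id"]]
        summaries.append(s)
        expandeds.append(e)
    return (pd.concat(summaries, ignore_index=True),
            pd.concat(expandeds, ignore_index=True))


@click.command(name="chromjet")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True),
              help="Contact map: dense text, .cool/.mcool or .hic")
@click.option("--chrom", required=True, help="Chromosome to process")
@click.option("--resolution", required=True, type=int, help="Bin size in bp")
@click.option("--exp", required=True, type=click.Choice(["hic", "replihic"]),
              help="Experiment type preset")
@click.option("--out", "outdir", default="chromjet_out", type=click.Path(),
              help="Output directory")
@click.option("--window", type=int, default=None, help="Max genomic distance (bp)")
@click.option("--norm", default=None, help="Normalization label")
@click.option("--gamma", type=float, default=None)
@click.option("--jet-widths", "jet_widths", nargs=2, type=float, default=None)
@click.option("--scale-range", "scale_range", default=None,
              help="Comma-separated explicit scales")
@click.option("--thresholds", nargs=2, type=float, default=None)
@click.option("--angle-range", nargs=2, type=float, default=None)
@click.option("--corner-trim", type=float, default=None)
@click.option("--angle-trim", type=float, default=None)
@click.option("--eig2-trim", type=float, default=None)
@click.option("--rem-k-strata", type=int, default=None)
@click.option("--root-within", type=float, default=None)
@click.option("--entropy-thresh", type=float, default=None)
@click.option("--rmse", type=float, default=None)
@click.option("--ang-frac/--no-ang-frac", default=True)
@click.option("--sum-cond", default=None)
@click.option("--agg", type=click.Choice(["sum", "mean"]), default=None)
@click.option("--alpha", multiple=True, type=float, help="May be given repeatedly")
@click.option("--saliency-thresh", type=float, default=None)
@click.option("--im-vmin", type=float, default=None)
@click.option("--im-vmax", type=float, default=None)
@click.option("--convolution-padding", default=None)
@click.option("--rotation-padding", default=None)
@click.option("--seed", type=int, default=0)
@click.option("-v", "--verbose", is_flag=True)
def cli(input_path, chrom, resolution, exp, outdir, verbose, seed, scale_range,
        ang_frac, alpha, **overrides):
    """Call chromatin jets in one chromosome of a contact map."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")
    if scale_range:
        overrides["scale_range"] = [float(x) for x in scale_range.split(",")]
    overrides = {k: (v if v not in ((), None) else None) for k, v in overrides.items()}
    config = preset_config(exp, resolution=resolution, seed=seed, ang_frac=ang_frac,
                           alpha=tuple(alpha) if alpha else None, **overrides)
    result = call_jets(input_path, config, chromosome=chrom)
    write_run(result, outdir)
    click.echo(f"{chrom}: {result.stage_counts} -> outputs in {outdir}")
    for a in config.alpha:
        n_sig = len(result.significant(a, config.saliency_thresh))
        click.echo(f"  alpha={a:g}, saliency_thresh={config.saliency_thresh:g}: "
                   f"{n_sig} significant jets")
    return 0


def cli_main(argv=None) -> int:
    """Entry point; returns the process exit code."""
    try:
        return cli.main(args=argv, standalone_mode=False) or 0
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except click.exceptions.Abort:
        return 1
    except SystemExit as exc:  # click usage errors re-raise SystemExit
        return int(exc.code or 0)


if __name__ == "__main__":
    sys.exit(cli_main())
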