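"""Orchestration: manifest -> full results bundle on disk.

``run_pipeline`` executes read -> normalize -> spectra -> band decomposition
-> peak detection -> interference statistics -> abundance analyses for one
cohort and writes every intermediate table, a run log, and a JSON summary.
``make_report`` renders the bundle into a markdown summary with plots.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import abundance, bands, interference, peaks, profile_io, spectral

logger = logging.getLogger("triadscan")


@dataclasses.dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Defaults carry the study conditions: 875 nm band threshold, 0.2-2.0 um
    periodicity search range, 30 CoC intervals for shorter/total events and
    17 for longer events, and a single seed for all stochastic steps.
    """

    manifest: str
    out_dir: str
    threshold_nm: float = bands.DEFAULT_THRESHOLD_NM
    l_range_um: tuple = (0.2, 2.0)
    n_intervals: dict = dataclasses.field(
        default_factory=lambda: dict(interference.N_INTERVALS)
    )
    seed: int = 0
    chance_rounds: int = 200
    genotype_groups: Optional[tuple] = None  # pair of genotype labels to compare

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "l_range_um" in raw:
            raw["l_range_um"] = tuple(raw["l_range_um"])
        if "genotype_groups" in raw and raw["genotype_groups"] is not None:
            raw["genotype_groups"] = tuple(raw["genotype_groups"])
        return cls(**raw)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and chromosome."""


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output paths ("the bundle")."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list = []
    bundle: dict = {"out_dir": str(out)}

    profiles = profile_io.read_manifest(config.manifest)
    if not profiles:
        raise PipelineError("stage=read: manifest lists no chromosomes")
    lengths = {p.chromosome_id: p.length_um for p in profiles}
    roles = profiles[0].roles

    # --- spectra ---------------------------------------------------------
    prominent_rows = []
    for p in profiles:
        for role in roles:
            try:
                spec = spectral.profile_spectrum(p, role)
            except Exception as exc:
                raise PipelineError(f"stage=spectra chromosome={p.chromosome_id}: {exc}") from exc
            res = spectral.top_two_periodicities(spec, config.l_range_um)
            prominent_rows.append(
                {
                    "chromosome_id": p.chromosome_id,
                    "channel": role,
                    "l1_um": res.l1_um,
                    "l2_um": res.l2_um,
                    "excluded_reason": res.reason,
                }
            )
            if not res.ok:
                run_log.append(f"spectra {p.chromosome_id}/{role}: excluded ({res.reason})")
    prominent = pd.DataFrame(prominent_rows)
    prominent.to_csv(out / "prominent_periodicities.csv", index=False)
    bundle["prominent_periodicities"] = str(out / "prominent_periodicities.csv")

    gmm_fits = {}
    for role in roles:
        vals = prominent.query("channel == @role")[["l1_um", "l2_um"]].to_numpy().ravel()
        vals = vals[~pd.isna(vals)].astype(float)
        if vals.size >= 10:
            fit = spectral.fit_gmm2(vals, seed=config.seed)
            gmm_fits[role] = {
                "means_um": fit.means.tolist(),
                "sds_um": fit.sds.tolist(),
                "weights": fit.weights.tolist(),
                "converged": fit.converged,
            }
    with open(out / "periodicity_gmm.json", "w") as fh:
        json.dump(gmm_fits, fh, indent=2, default=_json_default)
    bundle["periodicity_gmm"] = str(out / "periodicity_gmm.json")

    summed = {}
    for role in roles:
        dist = spectral.summed_periodicity_distribution(profiles, role, mode="experimental")
        summed[role] = dist
    pd.concat(
        [
            pd.DataFrame(
                {
                    "channel": role,
                    "wavelength_um": d.wavelengths_um,
                    "probability": d.probability,
                }
            )
            for role, d in summed.items()
        ]
    ).to_csv(out / "summed_periodicity.csv", index=False)
    bundle["summed_periodicity"] = str(out / "summed_periodicity.csv")

    # --- bands + peaks ---------------------------------------------------
    peak_rows = []
    peaksets: dict = {}
    for p in profiles:
        for role in roles:
            try:
                comp = bands.split_bands(p, role, threshold_nm=config.threshold_nm)
            except Exception as exc:
                raise PipelineError(
                    f"stage=decompose chromosome={p.chromosome_id}: {exc}"
                ) from exc
            for band in ("shorter", "longer"):
                ps = peaks.detect_band_peaks(comp, band)
                peaksets[(role, band, p.chromosome_id)] = ps
                for pos, kind, h in zip(ps.positions_um, ps.kinds, ps.heights):
                    peak_rows.append(
                        {
                            "chromosome_id": p.chromosome_id,
                            "channel": role,
                            "band": band,
                            "position_um": pos,
                            "kind": kind,
                            "height": h,
                        }
                    )
    pd.DataFrame(peak_rows).to_csv(out / "peaks.csv", index=False)
    bundle["peaks"] = str(out / "peaks.csv")

    # --- interference statistics ----------------------------------------
    summary: dict = {"config": dataclasses.asdict(config), "n_chromosomes": len(profiles)}
    coc_rows, spacing_rows = [], []
    for role in roles:
        for band in ("shorter", "longer", "total"):
            if band == "total":
                sets = [
                    peaksets[(role, b, p.chromosome_id)]
                    for p in profiles
                    for b in ("shorter", "longer")
                ]
                emap = interference.peaks_to_eventmap(sets, lengths, mode="union")
            else:
                sets = [peaksets[(role, band, p.chromosome_id)] for p in profiles]
                emap = interference.peaks_to_eventmap(sets, lengths)
            spac = interference.adjacent_spacings(emap)
            for s in spac:
                spacing_rows.append({"channel": role, "band": band, "spacing_um": s})
            key = f"{role}/{band}"
            stats_block = {"n_events": emap.n_events, "n_spacings": int(spac.size)}
            if spac.size >= 20:
                gfit = interference.fit_gamma(spac)
                stats_block["gamma"] = {
                    "alpha": gfit.alpha,
                    "scale_um": gfit.scale_um,
                    "mode_um": gfit.mode_um,
                }
                gmm = interference.fit_two_gaussian_spacings(spac, seed=config.seed)
                stats_block["two_gaussian_means_um"] = gmm.means.tolist()
            curve = interference.coc_curve(
                emap, n_intervals=config.n_intervals.get(band, 30)
            )
            stats_block["l_coc_um"] = interference.l_coc(curve)
            for dist, coc, npairs in zip(curve.distances_um, curve.coc, curve.n_pairs):
                coc_rows.append(
                    {
                        "channel": role,
                        "band": band,
                        "distance_um": dist,
                        "coc": coc,
                        "n_pairs": npairs,
                    }
                )
            summary[key] = stats_block

        # longer-vs-shorter relation per channel
        rel_log: list = []
        rel = interference.longer_vs_shorter_relation(
            {p.chromosome_id: peaksets[(role, "longer", p.chromosome_id)].positions_um for p in profiles},
            {p.chromosome_id: peaksets[(role, "shorter", p.chromosome_id)].positions_um for p in profiles},
            log=rel_log,
        )
        run_log.extend(f"longer_vs_shorter {role}: {m}" for m in rel_log)
        summary[f"{role}/longer_vs_shorter"] = {
            "median_um": rel.median_um,
            "fraction_ge_100nm": rel.fraction_ge_100nm,
            "median_count_ratio": rel.median_ratio,
            "n_peak_pairs": rel.n_peak_pairs,
        }

    # triad colocalization: nearest heterologous distances per band
    for band in ("shorter", "longer"):
        for a, b in (("crossover", "axis"), ("crossover", "sc"), ("axis", "sc")):
            if a not in roles or b not in roles:
                continue
            pa = {p.chromosome_id: peaksets[(a, band, p.chromosome_id)].positions_um for p in profiles}
            pb = {p.chromosome_id: peaksets[(b, band, p.chromosome_id)].positions_um for p in profiles}
            dists = interference.nearest_heterologous_distances(pa, pb)
            null = interference.chance_expectation(
                pa, pb, lengths, n_rounds=config.chance_rounds, seed=config.seed
            )
            summary[f"triad/{band}/{a}-{b}"] = {
                "modal_um": interference.modal_value(dists),
                "median_um": float(np.median(dists)) if dists.size else None,
                "chance_modal_um": null.mode_um,
                "chance_median_um": null.median_um,
                "n": int(dists.size),
            }

    pd.DataFrame(coc_rows).to_csv(out / "coc_curves.csv", index=False)
    pd.DataFrame(spacing_rows).to_csv(out / "spacings.csv", index=False)
    bundle["coc_curves"] = str(out / "coc_curves.csv")
    bundle["spacings"] = str(out / "spacings.csv")

    # --- abundance -------------------------------------------------------
    diss_log: list = []
    diss = abundance.dissimilarity_table(profiles, threshold_nm=config.threshold_nm, log=diss_log)
    run_log.extend(f"dissimilarity: {m}" for m in diss_log)
    diss.to_csv(out / "dissimilarity.csv", index=False)
    bundle["dissimilarity"] = str(out / "dissimilarity.csv")

    if config.genotype_groups and not diss.empty:
        ga, gb = config.genotype_groups
        comp = abundance.compare_groups(
            diss.query("genotype == @ga"), diss.query("genotype == @gb")
        )
        comp.to_csv(out / "group_comparison.csv", index=False)
        bundle["group_comparison"] = str(out / "group_comparison.csv")

    pop_frames = []
    for role in roles:
        pa = abundance.population_average(profiles, role)
        pa["channel"] = role
        pop_frames.append(pa)
    pd.concat(pop_frames).to_csv(out / "population_average.csv", index=False)
    bundle["population_average"] = str(out / "population_average.csv")

    abundance.mean_channel_intensity(profiles).to_csv(
        out / "mean_intensity.csv", index=False
    )
    bundle["mean_intensity"] = str(out / "mean_intensity.csv")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    bundle["summary"] = str(out / "summary.json")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(run_log) + ("\n" if run_log else ""))
    bundle["run_log"] = str(out / "run_log.txt")
    with open(out / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    return bundle


def make_report(bundle: dict, out_path=None) -> Path:
    """Render a bundle into a markdown report with summary plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(bundle["out_dir"])
    out_path = Path(out_path) if out_path else out_dir / "report.md"
    lines = ["# triadscan analysis report", ""]
    gaps = []

    if "summary" in bundle and Path(bundle["summary"]).exists():
        with open(bundle["summary"]) as fh:
            summary = json.load(fh)
        lines.append("## Interference statistics")
        lines.append("")
        lines.append("| channel/band | n events | gamma mode (um) | alpha | L_CoC (um) |")
        lines.append("|---|---|---|---|---|")
        for key, block in summary.items():
            if not isinstance(block, dict) or "n_events" not in block:
                continue
            g = block.get("gamma", {})
            lines.append(
                f"| {key} | {block['n_events']} | "
                f"{g.get('mode_um', float('nan')):.3f} | {g.get('alpha', float('nan')):.2f} | "
                f"{block.get('l_coc_um', float('nan'))} |"
            )
        lines.append("")
        triad_keys = [k for k in summary if k.startswith("triad/")]
        if triad_keys:
            lines.append("## Triad colocalization")
            lines.append("")
            for k in triad_keys:
                b = summary[k]
                lines.append(
                    f"- {k}: modal {b['modal_um']:.3f} um "
                    f"(chance {b['chance_modal_um']:.3f} um, n={b['n']})"
                )
            lines.append("")
    else:
        gaps.append("summary.json missing")

    if "coc_curves" in bundle and Path(bundle["coc_curves"]).exists():
        coc = pd.read_csv(bundle["coc_curves"])
        if coc.empty:
            gaps.append("coc_curves.csv empty")
        else:
            fig, ax = plt.subplots(figsize=(6, 4))
            for (channel, band), grp in coc.groupby(["channel", "band"]):
                ax.plot(grp["distance_um"], grp["coc"], label=f"{channel}/{band}", alpha=0.7)
            ax.axhline(1.0, color="gray", ls="--", lw=0.8)
            ax.axhline(0.5, color="gray", ls=":", lw=0.8)
            ax.set_xlabel("inter-interval distance (um)")
            ax.set_ylabel("CoC")
            ax.legend(fontsize=6)
            fig.tight_layout()
            fig.savefig(out_dir / "coc_curves.png", dpi=120)
            plt.close(fig)
            lines.append("![CoC curves](coc_curves.png)")
            lines.append("")
    else:
        gaps.append("coc_curves.csv missing")

    if "spacings" in bundle and Path(bundle["spacings"]).exists():
        spac = pd.read_csv(bundle["spacings"])
        if not spac.empty:
            fig, axes = plt.subplots(1, 2, figsize=(8, 3))
            for ax, band in zip(axes, ("shorter", "longer")):
                sub = spac.query("band == @band")["spacing_um"]
                if len(sub):
                    ax.hist(sub, bins=30)
                ax.set_title(f"{band} spacings")
                ax.set_xlabel("um")
            fig.tight_layout()
            fig.savefig(out_dir / "spacings.png", dpi=120)
            plt.close(fig)
            lines.append("![Spacing histograms](spacings.png)")
            lines.append("")

    if "summed_periodicity" in bundle and Path(bundle["summed_periodicity"]).exists():
        dist = pd.read_csv(bundle["summed_periodicity"])
        if not dist.empty:
            fig, ax = plt.subplots(figsize=(6, 3))
            for channel, grp in dist.groupby("channel"):
                ax.plot(grp["wavelength_um"], grp["probability"], label=channel)
            ax.set_xlim(0, 2.5)
            ax.set_xlabel("periodicity (um)")
            ax.set_ylabel("probability")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / "summed_periodicity.png", dpi=120)
            plt.close(fig)
            lines.append("![Summed periodicities](summed_periodicity.png)")
            lines.append("")

    if gaps:
        lines.append("## Gaps")
        lines.extend(f"- {g}" for g in gaps)
        lines.append("")
    out_path.write_text("\n".join(lines))
    return out_path
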