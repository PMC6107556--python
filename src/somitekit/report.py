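"""Statistical comparisons and end-to-end stage reports.

Group comparisons use the two-tailed Welch t-test (unequal variances,
Satterthwaite degrees of freedom). ``run_three_stage_scenario`` runs
the full synthetic pipeline for the early / mid / late regimes —
random, rostro-medially directed and slow inward motion with low,
high and very low proliferation — and ``build_report`` aggregates any
module outputs in a results directory into one deterministic JSON
plus figures. No multiple-testing correction is applied; p-values are
reported raw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sps

from .correlation import correlation_timecourse
from .divisions import detect_divisions_movie
from .io import VoxelGeometry
from .synth import TissueModel, simulate_movie, stage_preset
from .tracking import track_movie

__all__ = [
    "TestResult",
    "welch_ttest",
    "run_three_stage_scenario",
    "build_report",
]


@dataclass(frozen=True)
class TestResult:
    """Welch two-tailed t-test result."""

    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def welch_ttest(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-tailed t-test with unequal variances.

    Satterthwaite (fractional) degrees of freedom; each sample needs
    n ≥ 2 and nonzero variance. Identical samples give t = 0, p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate but well-defined: no evidence of a difference
        return TestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both samples are constant with different means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def run_three_stage_scenario(
    seed: int = 0,
    n_cells: int = 40,
    domain_um: tuple[float, float, float] = (110.0, 110.0, 4.0),
    n_frames: int = 8,
    snr: float = 10.0,
    division_domain_um: tuple[float, float, float] = (100.0, 100.0, 4.0),
    division_n_cells: int = 60,
) -> dict:
    """Run tracking, proliferation and correlation per stage.

    For each stage (early / mid / late) two movies are simulated with
    that stage's motion and division regime: a sparse dorsal-plane
    movie for tracking and a larger field for rounded-cell counting
    over 180 minutes. Returns a dict with per-stage mean speed,
    directionality R, mean track angle, proliferation rate and the
    centre-depth correlation, plus pairwise Welch tests on per-track
    speeds. Deterministic per seed.
    """
    geometry = VoxelGeometry()
    rng = np.random.default_rng(seed)
    out: dict = {"seed": seed, "stages": {}, "tests": {}}
    speeds_by_stage: dict[str, np.ndarray] = {}
    for i, stage in enumerate(("early", "mid", "late")):
        preset = stage_preset(stage, domain_um)
        stage_seed = int(rng.integers(0, 2**31 - 1))
        tissue = TissueModel(
            domain_um=domain_um,
            n_cells=n_cells,
            radius_mean_um=3.0,
            radius_sd_um=0.3,
        )
        seq, gt = simulate_movie(
            tissue,
            preset["motion"],
            n_frames,
            geometry,
            seed=stage_seed,
            render="plane",
            noise={"snr": snr},
        )
        tracks, tstats = track_movie(
            seq,
            expected_diameter_um=5.0,
            quality_threshold=0.01,
            max_link_distance_um=12.0,
        )
        corr = correlation_timecourse(
            seq,
            depth_fractions=[0.5],
            t0_min=0.0,
            t1_min=(n_frames - 1) * geometry.dt,
        )
        div_tissue = TissueModel(
            domain_um=division_domain_um,
            n_cells=division_n_cells,
            radius_mean_um=3.0,
            radius_sd_um=0.3,
            division_rate_per_hr=stage_preset(stage, division_domain_um)[
                "division_rate_per_hr"
            ],
        )
        div_seq, div_gt = simulate_movie(
            div_tissue,
            stage_preset(stage, division_domain_um)["motion"],
            n_frames,
            geometry,
            seed=stage_seed + 1,
            render="plane",
            noise={"snr": snr},
        )
        events, rate = detect_divisions_movie(div_seq)
        speeds = np.asarray(tstats["speeds_um_per_min"], float)
        speeds_by_stage[stage] = speeds
        out["stages"][stage] = {
            "n_tracks": tstats["n_tracks"],
            "mean_speed_um_per_min": float(speeds.mean()) if speeds.size else np.nan,
            "resultant_length": tstats.get("resultant_length", np.nan),
            "mean_angle_deg": tstats.get("mean_angle_deg", np.nan),
            "proliferation_rate_per_hr": rate,
            "true_division_events": int(len(div_gt.divisions)),
            "correlation_centre": corr[0].r,
            "angles_deg": list(map(float, tstats["angles_deg"])),
            "net_displacements_um": list(
                map(float, tstats["net_displacements_um"])
            ),
        }
    for pair in (("early", "mid"), ("mid", "late"), ("early", "late")):
        a, b = speeds_by_stage[pair[0]], speeds_by_stage[pair[1]]
        if a.size >= 2 and b.size >= 2:
            res = welch_ttest(a, b)
            out["tests"][f"speed_{pair[0]}_vs_{pair[1]}"] = {
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "unit": "per-track mean speed",
            }
    return out


def _radial_histogram_figure(angles_deg, path: Path) -> None:
    counts, edges = np.histogram(angles_deg, bins=np.linspace(-180, 180, 17))
    centres = np.radians((edges[:-1] + edges[1:]) / 2)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centres, counts, width=np.radians(22.5), edgecolor="k", alpha=0.7)
    ax.set_title("track angle distribution")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _length_angle_figure(stage_data: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for stage, colour in (("early", "k"), ("mid", "r"), ("late", "b")):
        d = stage_data.get(stage)
        if not d:
            continue
        ax.scatter(
            d.get("angles_deg", []),
            d.get("net_displacements_um", []),
            s=12,
            c=colour,
            label=stage,
        )
    ax.set_xlabel("track angle (deg)")
    ax.set_ylabel("net displacement (µm)")
    ax.legend()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _correlation_figure(stage_data: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    stages = [s for s in ("early", "mid", "late") if s in stage_data]
    ax.bar(stages, [stage_data[s].get("correlation_centre", np.nan) for s in stages])
    ax.set_ylabel("correlation r (t0 vs t_end)")
    ax.set_ylim(0, 1)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def build_report(results_dir: str | Path, out_path: str | Path | None = None) -> dict:
    """Aggregate module outputs in a directory into one JSON report.

    The known section files (``growth.json``, ``correlation.json``,
    ``divisions.json``, ``tracking.json``, ``domains.json``,
    ``scenario.json``) are collected when present and listed as absent
    when missing rather than failing. If a scenario section with per-stage track
    data is present, the radial-histogram, length-vs-angle and
    correlation figures are regenerated deterministically next to the
    report. Identical inputs produce byte-identical JSON.
    """
    results_dir = Path(results_dir)
    if not results_dir.is_dir():
        raise FileNotFoundError(results_dir)
    known = ("growth", "correlation", "divisions", "tracking", "domains", "scenario")
    sections: dict = {}
    for name in known:
        f = results_dir / f"{name}.json"
        if f.exists():
            with open(f) as fh:
                sections[name] = json.load(fh)
    if not sections:
        raise FileNotFoundError(f"no module outputs (*.json) found in {results_dir}")
    report = {
        "sections": sections,
        "absent": [k for k in known if k not in sections],
        "note": "p-values are reported raw; no multiple-testing correction applied",
    }
    out_path = Path(out_path) if out_path else results_dir / "report.json"
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    scenario = sections.get("scenario")
    if scenario and "stages" in scenario:
        stage_data = scenario["stages"]
        all_angles = [
            a for d in stage_data.values() for a in d.get("angles_deg", [])
        ]
        if all_angles:
            _radial_histogram_figure(all_angles, out_path.parent / "angles_radial.png")
        _length_angle_figure(stage_data, out_path.parent / "length_vs_angle.png")
        _correlation_figure(stage_data, out_path.parent / "correlation.png")
    return report
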