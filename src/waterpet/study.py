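"""Simulated-motion study orchestration and evaluation statistics.

`MotionStudy` runs the full design — a seeded population of motion-free
subjects, the 16-trajectory motion catalogue injected into each, and one or
more correction approaches — and aggregates the statistics used to judge
motion artifacts: relative MBF deviations against the motion-free reference,
large-artifact flags (> 20% territorial deviation), dichotomous clinical
interpretation at the 2.3 mL·min⁻¹·g⁻¹ stress-MBF cut-off, Wilcoxon
signed-rank heatmaps (median and maximum deviation per motion x territory),
residual-motion tables and Bland–Altman summaries.

Correction approaches
---------------------
``oracle``       ground-truth negation of the injected trajectory
``reader_pre``   reader emulation applied to every scan (motion assessed on
                 the raw dynamic frames)
``reader_post``  reader emulation applied only to scans whose uncorrected
                 analysis shows a large artifact (motion assessed on the
                 quantified results first) — a computational emulation of a
                 human workflow difference
``automatic``    normalized-cross-correlation shift estimation
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import __version__ as _pkg_version
from .aif import AIFModel
from .correction import (
    CorrectionSet,
    correct,
    estimate_shifts,
    oracle_correction,
    reader_model,
    residual_motion,
)
from .frames import FrameTimeGrid, build_frame_grid
from .kinetics import MBFResult, extract_aif, fit_parametric, territorial_mbf
from .motion import MotionTrajectory, apply_motion, build_catalogue, peak_frame
from .phantom import DynamicImage, GroundTruth, PhantomSpec, generate_phantom, population_specs

__all__ = [
    "relative_deviation",
    "DeviationReport",
    "interpret",
    "InterpretationRecord",
    "interpretation_change",
    "signed_rank_deviation_test",
    "significance_band",
    "bland_altman",
    "BlandAltman",
    "StudyDesign",
    "MotionStudy",
    "StudyResults",
    "run_study",
]

TERRITORIES = ("LAD", "RCA", "LCx")
REGIONS = TERRITORIES + ("global",)

#: Normal/abnormal stress-MBF cut-off, mL·min⁻¹·g⁻¹.
MBF_THRESHOLD = 2.3

#: Territorial relative deviation beyond which a scan counts as a large
#: motion artifact, percent.
LARGE_ARTIFACT_PERCENT = 20.0


def relative_deviation(mbf_test: float, mbf_ref: float) -> float:
    """Percentage difference 100·(test − ref)/ref against the motion-free
    reference."""
    if mbf_ref <= 0:
        raise ValueError("reference MBF must be positive")
    return 100.0 * (mbf_test - mbf_ref) / mbf_ref


@dataclass
class DeviationReport:
    """Relative deviations of one analysed scan vs its motion-free reference.

    ``large_artifact`` is true iff any coronary territory deviates by more
    than 20% before correction; ``artifact_reduced`` (when a corrected
    analysis is present) is true iff the worst territorial deviation shrank.
    """

    uncorrected: dict[str, float]                 # % per region
    corrected: Optional[dict[str, float]] = None

    @property
    def large_artifact(self) -> bool:
        return any(abs(self.uncorrected[t]) > LARGE_ARTIFACT_PERCENT for t in TERRITORIES)

    @property
    def artifact_reduced(self) -> Optional[bool]:
        if self.corrected is None:
            return None
        worst_pre = max(abs(self.uncorrected[t]) for t in TERRITORIES)
        worst_post = max(abs(self.corrected[t]) for t in TERRITORIES)
        return worst_post < worst_pre

    @classmethod
    def from_results(
        cls,
        test: MBFResult,
        ref: MBFResult,
        corrected: Optional[MBFResult] = None,
    ) -> "DeviationReport":
        def devs(r: MBFResult) -> dict[str, float]:
            d = {t: relative_deviation(r.territory_mbf[t], ref.territory_mbf[t]) for t in TERRITORIES}
            d["global"] = relative_deviation(r.global_mbf, ref.global_mbf)
            return d

        return cls(uncorrected=devs(test), corrected=devs(corrected) if corrected else None)


@dataclass(frozen=True)
class InterpretationRecord:
    """Dichotomous reading: positive (abnormal) iff MBF < threshold.

    A value exactly at the threshold is negative (normal, MBF >= cut-off).
    ``any_positive`` is true when the global value or any territory is
    positive.
    """

    calls: dict[str, bool]            # region -> positive?

    @property
    def any_positive(self) -> bool:
        return any(self.calls.values())

    def __getitem__(self, region: str) -> bool:
        return self.calls[region]


def interpret(result: MBFResult, threshold: float = MBF_THRESHOLD) -> InterpretationRecord:
    calls = {}
    for t in TERRITORIES:
        if t not in result.territory_mbf:
            raise ValueError(f"territory {t} missing from result")
        calls[t] = result.territory_mbf[t] < threshold
    calls["global"] = result.global_mbf < threshold
    return InterpretationRecord(calls=calls)


def interpretation_change(
    pre: InterpretationRecord,
    post: InterpretationRecord,
    truth: InterpretationRecord,
) -> dict[str, dict[str, object]]:
    """Per-region change accounting between pre- and post-correction readings.

    Returns, for every region plus the ``any`` aggregate, the change type
    (``none`` / ``pos_to_neg`` / ``neg_to_pos``) and whether the change was
    true (post-correction reading agrees with the motion-free truth).
    """
    out: dict[str, dict[str, object]] = {}
    items = [(r, pre[r], post[r], truth[r]) for r in REGIONS]
    items.append(("any", pre.any_positive, post.any_positive, truth.any_positive))
    for region, p, q, t in items:
        if p == q:
            change = "none"
        elif p and not q:
            change = "pos_to_neg"
        else:
            change = "neg_to_pos"
        out[region] = {"change": change, "true": (q == t) if change != "none" else None}
    return out


def signed_rank_deviation_test(deviations: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value that the paired deviations
    have zero median (exact for small n, normal approximation otherwise,
    no multiplicity correction).  All-zero differences give p = 1."""
    d = np.asarray(deviations, dtype=float)
    if d.size < 5:
        raise ValueError("need at least 5 paired values")
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(d, alternative="two-sided")
    return float(res.pvalue)


def significance_band(p: float) -> str:
    """Heatmap band for a signed-rank p-value."""
    if p < 0.005:
        return "<.005"
    if p < 0.05:
        return "<.05"
    return ">.05"


@dataclass(frozen=True)
class BlandAltman:
    """Agreement summary of paired values: differences are post − pre."""

    median_difference: float
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(pre: np.ndarray, post: np.ndarray) -> BlandAltman:
    """Median difference and 95% limits of agreement (mean ± 1.96·SD)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need paired arrays of equal length >= 2")
    d = post - pre
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    return BlandAltman(
        median_difference=float(np.median(d)),
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=d.size,
    )


# ---------------------------------------------------------------------------
# study design and orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Design of one simulated-motion study run."""

    n_subjects: int = 10
    seed: int = 0
    approaches: tuple[str, ...] = ("oracle", "reader_pre", "reader_post")
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    aif: AIFModel = field(default_factory=AIFModel)
    frame_structure: Optional[Sequence[tuple[int, float]]] = None
    territory_jitter: float = 0.15
    threshold: float = MBF_THRESHOLD
    reader_alpha: tuple[float, float, float] = (1.0, 0.5, 0.8)
    reader_detection_threshold: float = 5.0
    reader_jitter_mm: float = 1.0
    motion_families: Optional[tuple[str, ...]] = None   # None = all 16 motions
    motion_scale: float = 1.0                            # 0 nulls the catalogue

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        known = {"oracle", "reader_pre", "reader_post", "automatic"}
        bad = set(self.approaches) - known
        if bad:
            raise ValueError(f"unknown approaches: {sorted(bad)}")

    @property
    def grid(self) -> FrameTimeGrid:
        return build_frame_grid(self.frame_structure) if self.frame_structure else build_frame_grid()


class MotionStudy:
    """Runs a `StudyDesign` end to end; ``run()`` returns `StudyResults`.

    Subjects are generated one at a time (same draws as
    `generate_population`), analysed motion-free, then re-analysed for each
    injected motion and correction approach.  All territorial analyses use
    the motion-free ground-truth masks, and the input function is extracted
    from each analysed image over the eroded LV-cavity mask, so motion
    corrupts the input function exactly as it would an image-derived one.
    """

    def __init__(self, design: StudyDesign, verbose: bool = False):
        self.design = design
        self.verbose = verbose

    # -- single-scan analysis ------------------------------------------------

    @staticmethod
    def analyse(
        image: DynamicImage,
        truth: GroundTruth,
        aif_mask: Optional[np.ndarray] = None,
    ) -> MBFResult:
        """Quantify one dynamic image with fixed ground-truth masks."""
        mask = aif_mask if aif_mask is not None else MotionStudy.aif_mask(truth)
        aif_frames = extract_aif(image, mask)
        parametric = fit_parametric(image, aif_frames, truth.myocardium_mask)
        return territorial_mbf(parametric, truth.territory_masks)

    @staticmethod
    def aif_mask(truth: GroundTruth) -> np.ndarray:
        """LV-cavity mask eroded by one voxel (partial-volume guard)."""
        eroded = ndimage.binary_erosion(truth.lv_cavity_mask)
        return eroded if eroded.any() else truth.lv_cavity_mask

    def _corrections(
        self,
        approach: str,
        traj: MotionTrajectory,
        moved: DynamicImage,
        dev_unc: DeviationReport,
        scan_seed: int,
    ) -> CorrectionSet:
        d = self.design
        if approach == "oracle":
            return oracle_correction(traj)
        if approach == "automatic":
            return estimate_shifts(moved)
        reader = lambda: reader_model(  # noqa: E731
            traj,
            alpha=d.reader_alpha,
            detection_threshold=d.reader_detection_threshold,
            seed=scan_seed,
            jitter_mm=d.reader_jitter_mm,
        )
        if approach == "reader_pre":
            return reader()
        if approach == "reader_post":
            # reviews quantified results first; corrects only clear artifacts
            return reader() if dev_unc.large_artifact else CorrectionSet.zero(len(traj))
        raise ValueError(approach)

    # -- full run ------------------------------------------------------------

    def run(self) -> "StudyResults":
        d = self.design
        grid = d.grid
        specs = population_specs(d.n_subjects, d.seed, d.base_spec, d.territory_jitter)
        rows: list[dict] = []
        resid_rows: list[dict] = []
        interp_rows: list[dict] = []
        failures: list[dict] = []

        for si, spec in enumerate(specs):
            image, truth = generate_phantom(spec, aif=d.aif, grid=grid)
            aif_mask = self.aif_mask(truth)
            res_free = self.analyse(image, truth, aif_mask)
            truth_interp = interpret(res_free, d.threshold)
            rows.append(self._row(si, "none", "none", "motion-free", res_free, None))

            myo_tac = image.tac(truth.myocardium_mask)
            catalogue = build_catalogue(grid, peak_frame(myo_tac))
            if d.motion_families is not None:
                catalogue = [t for t in catalogue if t.family in d.motion_families]
            if d.motion_scale != 1.0:
                catalogue = [
                    MotionTrajectory(t.label, t.family, d.motion_scale * t.shifts)
                    if d.motion_scale > 0
                    else MotionTrajectory.zero(len(t), t.label)
                    for t in catalogue
                ]

            for mi, traj in enumerate(catalogue):
                scan_seed = int(np.random.SeedSequence((d.seed, 7, si, mi)).generate_state(1)[0] % (2**31))
                try:
                    moved = apply_motion(image, traj)
                    res_unc = self.analyse(moved, truth, aif_mask)
                except Exception as exc:  # record and continue
                    failures.append({"subject": si, "motion": traj.label, "stage": "uncorrected", "error": str(exc)})
                    continue
                dev_unc = DeviationReport.from_results(res_unc, res_free)
                rows.append(self._row(si, traj.label, traj.family, "uncorrected", res_unc, dev_unc.uncorrected))
                pre_interp = interpret(res_unc, d.threshold)

                for approach in d.approaches:
                    try:
                        corrections = self._corrections(approach, traj, moved, dev_unc, scan_seed)
                        corrected_img = correct(moved, corrections)
                        res_cor = self.analyse(corrected_img, truth, aif_mask)
                    except Exception as exc:
                        failures.append({"subject": si, "motion": traj.label, "stage": approach, "error": str(exc)})
                        continue
                    dev = DeviationReport.from_results(res_unc, res_free, corrected=res_cor)
                    rows.append(self._row(si, traj.label, traj.family, approach, res_cor, dev.corrected,
                                          large_artifact=dev.large_artifact,
                                          artifact_reduced=dev.artifact_reduced))
                    resid = residual_motion(traj, corrections)
                    resid_rows.append({
                        "subject": si, "motion": traj.label, "family": traj.family,
                        "approach": approach,
                        **{f"median_residual_{ax}_mm": v for ax, v in resid.median_per_axis.items()},
                        "corrected_any": bool(np.any(corrections.shifts_mm != 0)),
                    })
                    post_interp = interpret(res_cor, d.threshold)
                    changes = interpretation_change(pre_interp, post_interp, truth_interp)
                    for region, ch in changes.items():
                        interp_rows.append({
                            "subject": si, "motion": traj.label, "family": traj.family,
                            "approach": approach, "region": region,
                            "change": ch["change"], "true": ch["true"],
                        })
                if self.verbose:
                    print(f"subject {si + 1}/{len(specs)}  {traj.label:<16} done")

        mbf_long = pd.DataFrame(rows)
        return StudyResults(
            design=d,
            mbf_long=mbf_long,
            residuals=pd.DataFrame(resid_rows),
            interpretation=pd.DataFrame(interp_rows),
            failures=failures,
        )

    @staticmethod
    def _row(subject, motion, family, analysis, res: MBFResult, devs, **extra) -> dict:
        row = {
            "subject": subject, "motion": motion, "family": family, "analysis": analysis,
            **res.as_dict(),
        }
        if devs is not None:
            row.update({f"dev_{k.lower()}_pct": v for k, v in devs.items()})
        row.update(extra)
        return row


def run_study(design: StudyDesign, verbose: bool = False) -> "StudyResults":
    """Convenience wrapper: ``MotionStudy(design).run()``."""
    return MotionStudy(design, verbose=verbose).run()


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

class StudyResults:
    """Aggregated outputs of a study run.

    ``mbf_long`` holds one row per analysed scan (subject x motion x
    analysis) with territorial/global MBF and relative deviations; heatmap
    tables, residual-motion and interpretation-change summaries are derived
    views.
    """

    def __init__(self, design, mbf_long, residuals, interpretation, failures):
        self.design = design
        self.mbf_long = mbf_long
        self.residuals = residuals
        self.interpretation = interpretation
        self.failures = failures

    # -- derived tables ------------------------------------------------------

    def _dev_table(self, analysis: str, agg: str) -> pd.DataFrame:
        df = self.mbf_long[self.mbf_long.analysis == analysis]
        cols = {f"dev_{r.lower()}_pct": r for r in REGIONS}
        if agg == "max":
            # the single most-deviating subject: value with the largest magnitude
            def worst(s: pd.Series) -> float:
                return float(s.iloc[np.argmax(np.abs(s.to_numpy()))])
            tab = df.groupby("motion", sort=False)[list(cols)].agg(worst)
        else:
            tab = df.groupby("motion", sort=False)[list(cols)].median()
        return tab.rename(columns=cols)

    def heatmap_median(self, analysis: str = "uncorrected") -> pd.DataFrame:
        """Median relative deviation (%) per motion x region."""
        return self._dev_table(analysis, "median")

    def heatmap_max(self, analysis: str = "uncorrected") -> pd.DataFrame:
        """Signed maximum-magnitude relative deviation (%) per motion x region."""
        return self._dev_table(analysis, "max")

    def heatmap_p(self, analysis: str = "uncorrected") -> pd.DataFrame:
        """Wilcoxon signed-rank p per motion x region (raw, unbanded)."""
        df = self.mbf_long[self.mbf_long.analysis == analysis]
        out = {}
        for r in REGIONS:
            col = f"dev_{r.lower()}_pct"
            out[r] = df.groupby("motion", sort=False)[col].apply(
                lambda s: signed_rank_deviation_test(s.to_numpy())
                if s.size >= 5 else np.nan
            )
        return pd.DataFrame(out)

    def heatmap_bands(self, analysis: str = "uncorrected") -> pd.DataFrame:
        return self.heatmap_p(analysis).map(significance_band)

    def residual_table(self, approach: str) -> pd.DataFrame:
        """Median residual motion (mm) per motion x axis for one approach."""
        df = self.residuals[self.residuals.approach == approach]
        cols = [f"median_residual_{ax}_mm" for ax in ("x", "y", "z")]
        return df.groupby("motion", sort=False)[cols].median()

    def interpretation_table(self, approach: str) -> pd.DataFrame:
        """Counts of interpretation changes (and how many were true) per
        region for one approach."""
        df = self.interpretation[self.interpretation.approach == approach]
        rows = []
        for region in list(REGIONS) + ["any"]:
            sub = df[df.region == region]
            for change in ("pos_to_neg", "neg_to_pos"):
                ch = sub[sub.change == change]
                rows.append({
                    "region": region, "change": change,
                    "changed": int(len(ch)),
                    "true": int(ch["true"].fillna(False).sum()),
                })
        return pd.DataFrame(rows)

    def bland_altman_summary(self, approach: str) -> dict[str, BlandAltman]:
        """Pre- vs post-correction agreement per region across motion scans."""
        pre = self.mbf_long[self.mbf_long.analysis == "uncorrected"]
        post = self.mbf_long[self.mbf_long.analysis == approach]
        key = ["subject", "motion"]
        merged = pre.merge(post, on=key, suffixes=("_pre", "_post"))
        out = {}
        for r in REGIONS:
            col = f"mbf_{r.lower()}"
            out[r] = bland_altman(merged[f"{col}_pre"].to_numpy(), merged[f"{col}_post"].to_numpy())
        return out

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        d = self.design
        n_motion = int((self.mbf_long.analysis == "uncorrected").sum())
        lines = [
            "Simulated-motion study",
            "=" * 50,
            f"subjects: {d.n_subjects}   motion scans: {n_motion}   seed: {d.seed}",
            f"approaches: {', '.join(d.approaches)}   threshold: {d.threshold} mL/min/g",
        ]
        free = self.mbf_long[self.mbf_long.analysis == "motion-free"]["mbf_global"]
        lines.append(
            f"motion-free global MBF: median {free.median():.2f} "
            f"(IQR {free.quantile(0.75) - free.quantile(0.25):.2f}) mL/min/g"
        )
        unc = self.mbf_long[self.mbf_long.analysis == "uncorrected"]
        if len(unc):
            large = (
                unc[[f"dev_{t.lower()}_pct" for t in TERRITORIES]].abs().max(axis=1)
                > LARGE_ARTIFACT_PERCENT
            )
            lines.append(f"large-artifact scans (>20% territorial deviation): {int(large.sum())}/{len(unc)}")
        for ap in d.approaches:
            med = self.heatmap_median(ap)
            if len(med):
                lines.append(f"{ap}: worst |median deviation| after correction "
                             f"{np.abs(med.to_numpy()).max():.1f}%")
        if self.failures:
            lines.append(f"failed stages: {len(self.failures)}")
        return "\n".join(lines)

    def to_dir(self, out_dir: str | Path) -> None:
        """Persist all tables (CSV) plus design/provenance (JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mbf_long.to_csv(out / "mbf_long.csv", index=False)
        self.residuals.to_csv(out / "residual_motion.csv", index=False)
        self.interpretation.to_csv(out / "interpretation_changes.csv", index=False)
        analyses = ["uncorrected", *self.design.approaches]
        for analysis in analyses:
            self.heatmap_median(analysis).to_csv(out / f"heatmap_median_{analysis}.csv")
            self.heatmap_max(analysis).to_csv(out / f"heatmap_max_{analysis}.csv")
            self.heatmap_p(analysis).to_csv(out / f"heatmap_p_{analysis}.csv")
        design = asdict(self.design)
        design["base_spec"]["grid_shape"] = list(design["base_spec"]["grid_shape"])
        meta = {
            "package_version": _pkg_version,
            "design": _jsonable(design),
            "n_failures": len(self.failures),
            "failures": self.failures,
        }
        (out / "study.json").write_text(json.dumps(meta, indent=2))

    def plot_heatmap(self, analysis: str = "uncorrected", kind: str = "median", ax=None):
        """Matplotlib heatmap of median/max deviation per motion x region."""
        import matplotlib.pyplot as plt

        tab = self.heatmap_median(analysis) if kind == "median" else self.heatmap_max(analysis)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        vmax = max(np.abs(tab.to_numpy()).max(), 1.0)
        im = ax.imshow(tab.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xticks(range(len(tab.columns)), tab.columns)
        ax.set_yticks(range(len(tab.index)), tab.index)
        ax.set_title(f"{kind} relative deviation (%) — {analysis}")
        plt.colorbar(im, ax=ax, label="%")
        return ax


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
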