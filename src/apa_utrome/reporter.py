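"""Dual-fluorophore (GFP/mCherry) integrated-density ratio quantification.

The miRNA-escape sensor is a bicistronic reporter: mCherry reports
transcription of the construct while a destabilized GFP carries the 3'UTR
under test, so miRNA repression shows up as a depressed GFP/mCherry ratio.
Per channel, the background-corrected integrated density is

    ID_t - (ID_b / Area_b) x Area_t - ID_N2

where ID_t is the integrated density of the animal image, ID_b that of a
small background selection of area Area_b, Area_t the pixel count of the
entire image, and ID_N2 the mean integrated density of non-fluorescent
control animals. The reported statistic is corrected GFP over corrected
mCherry; group comparisons use a two-sided paired t-test on per-animal
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ChannelMeasurement:
    id_total: float
    id_background: float
    area_background: float
    area_total: float
    id_n2_baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.area_background <= 0:
            raise ValueError("background selection area must be positive")
        if self.area_total <= 0:
            raise ValueError("total image area must be positive")
        if min(self.id_total, self.id_background, self.id_n2_baseline) < 0:
            raise ValueError("integrated densities must be non-negative")


@dataclass(frozen=True)
class RatioResult:
    ratio: float | None
    numerator: float
    denominator: float
    valid: bool


def corrected_density(m: ChannelMeasurement) -> float:
    """Background- and baseline-corrected integrated density of one channel."""
    return m.id_total - (m.id_background / m.area_background) * m.area_total - m.id_n2_baseline


def gfp_mcherry_ratio(gfp: ChannelMeasurement, mcherry: ChannelMeasurement) -> RatioResult:
    """Corrected GFP over corrected mCherry; non-positive mCherry is invalid."""
    num = corrected_density(gfp)
    den = corrected_density(mcherry)
    if den <= 0:
        return RatioResult(ratio=None, numerator=num, denominator=den, valid=False)
    return RatioResult(ratio=num / den, numerator=num, denominator=den, valid=True)


def measure_from_images(
    gfp_image: np.ndarray,
    mcherry_image: np.ndarray,
    worm_mask: np.ndarray,
    background_mask: np.ndarray,
    n2_baselines: tuple[float, float] = (0.0, 0.0),
) -> tuple[ChannelMeasurement, ChannelMeasurement]:
    """Integrated densities over pixel masks for both channels.

    ``worm_mask`` selects the animal, ``background_mask`` a dark region;
    Area_t is the whole-image pixel count. ``n2_baselines`` carries the
    (GFP, mCherry) means from non-fluorescent control animals.
    """
    gfp_image = np.asarray(gfp_image, dtype=float)
    mcherry_image = np.asarray(mcherry_image, dtype=float)
    if gfp_image.shape != mcherry_image.shape:
        raise ValueError("channel images must have the same shape")
    worm_mask = np.asarray(worm_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if worm_mask.shape != gfp_image.shape or background_mask.shape != gfp_image.shape:
        raise ValueError("masks must match the image shape")
    if not worm_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    area_total = float(gfp_image.size)
    area_b = float(background_mask.sum())
    out = []
    for img, baseline in ((gfp_image, n2_baselines[0]), (mcherry_image, n2_baselines[1])):
        out.append(
            ChannelMeasurement(
                id_total=float(img[worm_mask].sum()),
                id_background=float(img[background_mask].sum()),
                area_background=area_b,
                area_total=area_total,
                id_n2_baseline=float(baseline),
            )
        )
    return out[0], out[1]


def paired_ratio_test(ratios_a, ratios_b) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-animal ratios -> (t, p)."""
    res = stats.ttest_rel(np.asarray(ratios_a, float), np.asarray(ratios_b, float))
    return float(res.statistic), float(res.pvalue)


def simulate_reporter_batch(
    n_animals: int = 30,
    gfp_repression: float = 1.0,
    seed: int = 0,
    base_intensity: float = 2000.0,
    noise_cv: float = 0.1,
) -> dict:
    """Simulate matched control/test animals with a planted GFP repression.

    Each animal pair shares an illumination/expression factor; the test
    construct's GFP signal is divided by ``gfp_repression``. Returns the
    per-animal ratios for both groups and the paired t-test against the
    control group.
    """
    rng = np.random.default_rng(seed)
    control, test = [], []
    for _ in range(n_animals):
        scale = rng.lognormal(0.0, 0.3)
        for group, repression in ((control, 1.0), (test, gfp_repression)):
            gfp_signal = base_intensity * scale / repression
            mch_signal = base_intensity * scale
            bg = 50.0 * scale
            gfp = ChannelMeasurement(
                id_total=(gfp_signal + bg) * max(0.1, rng.normal(1.0, noise_cv)),
                id_background=bg * 0.25 * max(0.1, rng.normal(1.0, noise_cv)),
                area_background=25.0,
                area_total=100.0,
                id_n2_baseline=0.0,
            )
            mch = ChannelMeasurement(
                id_total=(mch_signal + bg) * max(0.1, rng.normal(1.0, noise_cv)),
                id_background=bg * 0.25 * max(0.1, rng.normal(1.0, noise_cv)),
                area_background=25.0,
                area_total=100.0,
                id_n2_baseline=0.0,
            )
            group.append(gfp_mcherry_ratio(gfp, mch).ratio)
    t, p = paired_ratio_test(test, control)
    return {
        "control_ratios": control,
        "test_ratios": test,
        "mean_control": float(np.mean(control)),
        "mean_test": float(np.mean(test)),
        "t_statistic": t,
        "p_value": p,
    }
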