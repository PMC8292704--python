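"""Equivalence statistics for paired amplitude measurements.

Two imaging modalities measure the same programmed motions; the
agreement analysis works on the paired differences d_i = a_i - b_i
(convention: a = 4D CT, b = 4D CBCT, so a negative mean difference
means CBCT reads larger). It reports descriptive statistics, RMSE,
Shapiro-Wilk normality, the two one-sided t-test (TOST) of equivalence
within +/-1 mm, and correlation/regression of measured against
programmed amplitude.

The package ships transcriptions of the benchmark measurement tables
(``data/table1.csv``: 27 sine-motion scenarios, 21 of them with both
curve fits; ``data/table2.csv``: 7 patient waveforms x 3 axes). One
printed rounding quirk is preserved as printed: patient 3's SI absolute
difference is listed as 6.2 although the rounded per-modality columns
give |5.5 - 11.6| = 6.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "EquivalenceConfig",
    "EquivalenceReport",
    "summarize_paired",
    "shapiro_wilk",
    "tost",
    "correlate",
    "equivalence_report",
    "load_table1",
    "load_table2",
    "table1_statistics",
    "table2_statistics",
]


@dataclass
class PairedSample:
    """Paired amplitudes (mm) from two modalities; d = a - b."""

    labels: list[str]
    a: np.ndarray  # modality 1 (4D CT)
    b: np.ndarray  # modality 2 (4D CBCT)
    programmed: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.a) != len(self.b) or len(self.a) != len(self.labels):
            raise ValueError("labels, a and b must have equal length")
        if len(self.a) < 2:
            raise ValueError("need at least 2 pairs")
        if self.programmed is not None:
            self.programmed = np.asarray(self.programmed, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return self.a - self.b

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class EquivalenceConfig:
    """TOST equivalence margin (mm) and test level."""

    lower: float = -1.0
    upper: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValueError("lower limit must be below upper limit")


@dataclass
class EquivalenceReport:
    n: int
    mean_d: float
    sd_d: float
    se_d: float
    ci95_halfwidth: float
    rmse: float
    shapiro_W: float
    shapiro_p: float
    tost_p: float
    tost_equivalent: bool
    pearson_r: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    direction: str = "CT - CBCT"

    def to_markdown(self) -> str:
        lines = [
            "| statistic | value |",
            "|---|---|",
            f"| n pairs | {self.n} |",
            f"| mean difference ({self.direction}) | {self.mean_d:.2f} mm |",
            f"| SD of differences | {self.sd_d:.2f} mm |",
            f"| SE of mean difference | {self.se_d:.2f} mm |",
            f"| 95% CI half-width | {self.ci95_halfwidth:.2f} mm |",
            f"| RMSE | {self.rmse:.2f} mm |",
            f"| Shapiro-Wilk W (p) | {self.shapiro_W:.4f} ({self.shapiro_p:.2f}) |",
            f"| TOST p | {self.tost_p:.2e} |",
            f"| equivalent within margin | {self.tost_equivalent} |",
        ]
        if self.pearson_r is not None:
            lines += [
                f"| Pearson r vs programmed | {self.pearson_r:.4f} |",
                f"| R^2 vs programmed | {self.r_squared:.4f} |",
                f"| regression slope / intercept | "
                f"{self.slope:.4f} / {self.intercept:.4f} |",
            ]
        return "\n".join(lines)


def summarize_paired(d) -> dict[str, float]:
    """Descriptives of paired differences: mean, sample SD (n-1), SE,
    t-based 95% CI half-width, and RMSE = sqrt(mean(d^2))."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    se_d = sd_d / np.sqrt(n)
    ci = float(sps.t.ppf(0.975, n - 1) * se_d) if sd_d > 0 else 0.0
    rmse = float(np.sqrt(np.mean(d**2)))
    return {
        "n": n,
        "mean_d": mean_d,
        "sd_d": sd_d,
        "se_d": float(se_d),
        "ci95_halfwidth": ci,
        "rmse": rmse,
    }


def shapiro_wilk(d) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's AS R94 approximation, 3<=n<=5000)."""
    d = np.asarray(d, dtype=float)
    if not 3 <= len(d) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    W, p = sps.shapiro(d)
    return float(W), float(p)


def tost(d, cfg: EquivalenceConfig = EquivalenceConfig()) -> dict:
    """Two one-sided t-tests of mean(d) against the equivalence margin.

    t_lower tests mean > lower limit (p = upper tail), t_upper tests
    mean < upper limit (p = lower tail); the TOST p-value is the larger
    of the two, and equivalence is declared when it is below alpha.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("TOST undefined for zero-variance differences")
    se = sd / np.sqrt(n)
    t_lower = (d.mean() - cfg.lower) / se
    t_upper = (d.mean() - cfg.upper) / se
    p_lower = float(sps.t.sf(t_lower, n - 1))
    p_upper = float(sps.t.cdf(t_upper, n - 1))
    tost_p = max(p_lower, p_upper)
    return {
        "t_lower": float(t_lower),
        "p_lower": p_lower,
        "t_upper": float(t_upper),
        "p_upper": p_upper,
        "tost_p": tost_p,
        "equivalent": bool(tost_p < cfg.alpha),
    }


def correlate(x, y) -> dict[str, float]:
    """Pearson r, OLS slope/intercept of y on x, and R^2 = r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.linregress(x, y)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }


def equivalence_report(
    s: PairedSample, cfg: EquivalenceConfig = EquivalenceConfig()
) -> EquivalenceReport:
    """Full agreement analysis of a paired sample (plus regression
    against programmed amplitude when available)."""
    d = s.d
    summ = summarize_paired(d)
    W, p = shapiro_wilk(d)
    t = tost(d, cfg)
    reg = (
        correlate(s.programmed, s.a) if s.programmed is not None else None
    )
    return EquivalenceReport(
        n=summ["n"],
        mean_d=summ["mean_d"],
        sd_d=summ["sd_d"],
        se_d=summ["se_d"],
        ci95_halfwidth=summ["ci95_halfwidth"],
        rmse=summ["rmse"],
        shapiro_W=W,
        shapiro_p=p,
        tost_p=t["tost_p"],
        tost_equivalent=t["equivalent"],
        pearson_r=None if reg is None else reg["pearson_r"],
        slope=None if reg is None else reg["slope"],
        intercept=None if reg is None else reg["intercept"],
        r_squared=None if reg is None else reg["r_squared"],
    )


# ---------------------------------------------------------------------------
# bundled benchmark tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("traj4d.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Sine-motion scenarios: programmed amplitude/cycle time with 4D CT
    and 4D CBCT curve-fit amplitudes (mm) and the CT envelope reading;
    scenarios defeated by artifacts carry NaNs."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return pd.read_csv(p)


def load_table2() -> pd.DataFrame:
    """Patient-waveform amplitudes per axis for both modalities (mm)."""
    with resources.as_file(_data_path("table2.csv")) as p:
        return pd.read_csv(p)


def table1_statistics(
    cfg: EquivalenceConfig = EquivalenceConfig(),
) -> dict[str, float]:
    """Recompute the sine-motion agreement statistics from the bundled
    table: paired descriptives, Shapiro-Wilk, TOST, correlations of both
    modalities against programmed amplitude, and max |difference|."""
    df = load_table1()
    paired = df.dropna(subset=["ct_fit_mm", "cbct_fit_mm"])
    sample = PairedSample(
        labels=[
            f"{r.programmed_mm:g}mm/{r.cycle_time_s:g}s" for r in paired.itertuples()
        ],
        a=paired["ct_fit_mm"].to_numpy(),
        b=paired["cbct_fit_mm"].to_numpy(),
        programmed=paired["programmed_mm"].to_numpy(),
    )
    rep = equivalence_report(sample, cfg)
    cbct_all = df.dropna(subset=["cbct_fit_mm"])
    reg_cbct = correlate(cbct_all["programmed_mm"], cbct_all["cbct_fit_mm"])
    out = {
        "n_pairs": rep.n,
        "mean_difference_mm": rep.mean_d,
        "sd_difference_mm": rep.sd_d,
        "se_difference_mm": rep.se_d,
        "ci95_halfwidth_mm": rep.ci95_halfwidth,
        "rmse_mm": rep.rmse,
        "shapiro_W": rep.shapiro_W,
        "shapiro_p": rep.shapiro_p,
        "tost_p": rep.tost_p,
        "tost_equivalent": rep.tost_equivalent,
        "pearson_r_ct": rep.pearson_r,
        "r_squared_ct": rep.r_squared,
        "pearson_r_cbct": reg_cbct["pearson_r"],
        "r_squared_cbct": reg_cbct["r_squared"],
        "max_abs_difference_mm": float(np.abs(sample.d).max()),
    }
    return out


def table2_statistics() -> dict[str, float]:
    """Mean +/- sample SD of the printed per-axis absolute differences
    between modalities for the patient waveforms, with and without the
    outlier patient (patient 3, SI)."""
    df = load_table2()
    out: dict[str, float] = {}
    for axis in ("si", "ap", "lr"):
        d = df[f"{axis}_absdiff_mm"].to_numpy(float)
        out[f"{axis}_mean_mm"] = float(d.mean())
        out[f"{axis}_sd_mm"] = float(d.std(ddof=1))
    no_outlier = df[df["patient"] != 3]["si_absdiff_mm"].to_numpy(float)
    out["si_mean_no_outlier_mm"] = float(no_outlier.mean())
    out["si_sd_no_outlier_mm"] = float(no_outlier.std(ddof=1))
    return out
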