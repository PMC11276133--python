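"""Evaluation protocol: CNR, Potter grading, error metrics, ICC, and
subject-level 4-fold cross-validation of the enhancement + counting cascade.

Potter's scale grades the ePVS burden of a part by its count: 0 (none),
1 (1-10, mild), 2 (11-20, moderate), 3 (21-40, frequent), 4 (>40, severe).
A subject's grade is the maximum over its six part grades. Contrast-to-noise
ratio (CNR) is |mu_signal - mu_surround| / sigma_background, with the
surround taken as a 3-px ring around the ePVS mask and the background noise
estimated in a frame at the part border.

Reliability between predicted and reference grades is summarized by the
two-way random-effects, absolute-agreement, single-measure intraclass
correlation coefficient ICC(2,1) with an F-based 95% confidence interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
import scipy.stats

# ---------------------------------------------------------------------------
# Potter grading
# ---------------------------------------------------------------------------

#: count brackets per grade; None = unbounded above
GRADE_BRACKETS: dict[int, tuple[int, int | None]] = {
    0: (0, 0),
    1: (1, 10),
    2: (11, 20),
    3: (21, 40),
    4: (41, None),
}


def grade_from_count(count: float) -> int:
    """Potter grade for a (possibly real-valued) ePVS count.

    Real predictions are rounded half-up to an integer before bracket lookup.
    """
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    c = int(np.floor(count + 0.5))
    for grade, (lo, hi) in GRADE_BRACKETS.items():
        if c >= lo and (hi is None or c <= hi):
            return grade
    raise AssertionError("unreachable: brackets partition the nonnegative integers")


def subject_grade(part_grades) -> int:
    """Subject-level grade: the maximum of exactly six part grades."""
    grades = list(part_grades)
    if len(grades) != 6:
        raise ValueError(f"expected 6 part grades, got {len(grades)}")
    for g in grades:
        if not (0 <= int(g) <= 4):
            raise ValueError(f"grade {g} outside 0-4")
    return int(max(grades))


# ---------------------------------------------------------------------------
# Contrast-to-noise ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNRResult:
    mu_signal1: float  # mean intensity in the ePVS region
    mu_signal2: float  # mean intensity in the surrounding ring
    sigma_noise: float  # std of the background region
    cnr: float


def compute_cnr(image, signal_mask, surround_mask, background_mask) -> CNRResult:
    """CNR = |mu_signal - mu_surround| / sigma_background on explicit regions.

    The three masks must be nonempty and pairwise disjoint.
    """
    image = np.asarray(image, dtype=float)
    masks = {
        "signal": np.asarray(signal_mask, bool),
        "surround": np.asarray(surround_mask, bool),
        "background": np.asarray(background_mask, bool),
    }
    for name, m in masks.items():
        if m.shape != image.shape:
            raise ValueError(f"{name} mask shape {m.shape} != image shape {image.shape}")
        if not m.any():
            raise ValueError(f"{name} mask is empty")
    pairs = [("signal", "surround"), ("signal", "background"), ("surround", "background")]
    for a, b in pairs:
        if (masks[a] & masks[b]).any():
            raise ValueError(f"{a} and {b} masks overlap")
    mu1 = float(image[masks["signal"]].mean())
    mu2 = float(image[masks["surround"]].mean())
    sigma = float(image[masks["background"]].std())
    if sigma == 0.0:
        raise ValueError("background has zero variance; CNR undefined")
    return CNRResult(mu1, mu2, sigma, abs(mu1 - mu2) / sigma)


def cnr_regions_from_mask(mask, ring_width: int = 3, border: int = 8):
    """Default region geometry: surround = 3-px dilation ring around the ePVS
    mask; background = a `border`-px frame at the part edge minus both.

    Returns (signal, surround, background) boolean masks.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("ePVS mask is empty; no signal region")
    structure = np.ones((3, 3), bool)
    ring = ndi.binary_dilation(mask, structure, iterations=ring_width) & ~mask
    frame = np.zeros_like(mask)
    b = min(border, (min(mask.shape) - 1) // 2)
    frame[:b, :] = frame[-b:, :] = True
    frame[:, :b] = frame[:, -b:] = True
    background = frame & ~mask & ~ring
    if not background.any():
        raise ValueError("background frame is empty after excluding signal/surround")
    return mask, ring & ~background, background


def part_cnr(image, mask, ring_width: int = 3, border: int = 8) -> CNRResult:
    signal, surround, background = cnr_regions_from_mask(mask, ring_width, border)
    return compute_cnr(image, signal, surround, background)


# ---------------------------------------------------------------------------
# Error metrics and accuracy
# ---------------------------------------------------------------------------

def _paired(truth, pred):
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"truth and pred must be equal-length 1D, got {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty inputs")
    return t, p


def mae(truth, pred) -> float:
    t, p = _paired(truth, pred)
    return float(np.mean(np.abs(t - p)))


def mse(truth, pred) -> float:
    t, p = _paired(truth, pred)
    return float(np.mean((t - p) ** 2))


def grade_accuracy(truth_grades, pred_grades) -> float:
    """Percentage of exact grade matches."""
    t, p = _paired(truth_grades, pred_grades)
    return float(100.0 * np.mean(t == p))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def icc(truth, pred, form: str = "agreement", alpha: float = 0.05):
    """Single-measure ICC between two ratings of the same targets.

    form="agreement": two-way random effects, absolute agreement, ICC(2,1)
    (the default used for reporting); form="consistency": ICC(3,1).
    Returns (estimate, ci_low, ci_high) with an F-based (1-alpha) CI.
    """
    t, p = _paired(truth, pred)
    n = t.size
    if n < 5:
        raise ValueError("need at least 5 paired ratings")
    data = np.column_stack([t, p])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mserr = max(sse / ((n - 1) * (k - 1)), 0.0)
    fdist = scipy.stats.f
    if form == "consistency":
        est = (msr - mserr) / (msr + (k - 1) * mserr)
        if mserr == 0.0:
            return float(est), float(est), float(est)
        f_obs = msr / mserr
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / fdist.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * fdist.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
        return float(est), float(lo), float(hi)
    if form != "agreement":
        raise ValueError(f"unknown ICC form {form!r}")
    denom = msr + (k - 1) * mserr + (k / n) * (msc - mserr)
    est = (msr - mserr) / denom
    if mserr == 0.0 and msc == mserr:
        return float(est), float(est), float(est)
    # F-based CI (two-way random, absolute agreement, single measure)
    a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mserr) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mserr) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = fdist.ppf(1 - alpha / 2, n - 1, v)
        f2 = fdist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mserr) / (f1 * (k * msc + (k * n - k - n) * mserr) + n * msr)
        hi = n * (f2 * msr - mserr) / (k * msc + (k * n - k - n) * mserr + n * f2 * msr)
    else:
        lo = hi = est
    return float(est), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: dict[str, int]  # subject_id -> fold index

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f != fold)


def make_folds(subject_ids, k: int = 4, seed: int = 0) -> FoldPlan:
    """Seeded subject-level partition into k folds with sizes differing by <= 1."""
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    assignments = {}
    for pos, sid in enumerate(order):
        assignments[sid] = pos % k
    return FoldPlan(k=k, assignments=assignments)


# ---------------------------------------------------------------------------
# Cross-validated cascade evaluation
# ---------------------------------------------------------------------------

METHODS = ("none", "tophat", "clahe", "laplacian", "dl")


@dataclass
class EvalReport:
    method: str
    k: int
    seed: int
    count_max: int
    pooled_mae: float
    pooled_mse: float
    image_accuracy: float  # percent, exact grade matches over pooled test parts
    subject_accuracy: float  # percent, on max-aggregated grades
    icc_image: tuple[float, float, float]
    icc_subject: tuple[float, float, float]
    mean_cnr_enhanced: float
    mean_cnr_input: float
    per_fold_mae: list[float]
    n_images: int
    n_subjects: int
    predictions: "pandas.DataFrame"

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self) if f.name != "predictions"}
        d["icc_image"] = list(self.icc_image)
        d["icc_subject"] = list(self.icc_subject)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _enhance_images(method, images, enhancer_model, baseline_config):
    from . import baseline_enhance as be
    from . import models as m

    if method == "none":
        return list(images)
    if method == "dl":
        return m.enhance_batch(enhancer_model, list(images))
    cfg = baseline_config or be.BaselineConfig()
    fn = {
        "tophat": lambda im: be.tophat_enhance(im, cfg.tophat_radius),
        "clahe": lambda im: be.clahe_enhance(im, cfg.clahe_clip_limit, cfg.clahe_tile_grid),
        "laplacian": lambda im: be.laplacian_enhance(im, cfg.laplacian_weight),
    }[method]
    return [fn(im) for im in images]


def run_cross_validation(
    cohort,
    method: str = "dl",
    train_config=None,
    *,
    k: int = 4,
    seed: int = 0,
    out_shape=(80, 96),
    count_max: int = 48,
    baseline_config=None,
    cnr_border: int = 8,
) -> EvalReport:
    """Subject-level k-fold cross-validation of the full cascade.

    Per fold: for method "dl" an enhancer is trained on the training
    subjects' enhancement pairs and applied to both splits; algorithmic
    baselines are applied directly. A quantifier is then trained on the
    (enhanced) training images and evaluated on the held-out subjects.
    Pooled test predictions feed MAE/MSE, image- and subject-level grade
    accuracy, and ICC; mean CNR is measured on the enhanced test images.
    """
    import pandas as pd

    from . import models as m
    from . import preprocess as pp

    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    train_config = train_config or m.preset("desk")
    prepared = {}  # subject_id -> list of (part, PreparedPart)
    for rec in cohort:
        prepared[rec.subject_id] = [(p, pp.prepare_part(p, out_shape=out_shape, count_max=count_max)) for p in rec.parts]
    plan = make_folds(sorted(prepared), k=k, seed=seed)

    rows = []
    cnr_enh_all, cnr_in_all = [], []
    per_fold_mae = []
    for fold in range(k):
        train_ids = plan.train_subjects(fold)
        test_ids = plan.test_subjects(fold)
        train_parts = [pair for sid in train_ids for pair in prepared[sid]]
        test_parts = [pair for sid in test_ids for pair in prepared[sid]]
        fold_seed = int((seed + 9973 * (fold + 1)) % 2**31)
        cfg = replace(train_config, seed=fold_seed)

        enhancer = None
        if method == "dl":
            pairs = [(pp_.input_image, pp_.target) for _, pp_ in train_parts]
            enhancer, _ = m.train_enhancer(pairs, cfg)

        train_imgs = _enhance_images(method, [pp_.input_image for _, pp_ in train_parts], enhancer, baseline_config)
        test_imgs = _enhance_images(method, [pp_.input_image for _, pp_ in test_parts], enhancer, baseline_config)
        labels = [pp_.label.normalized for _, pp_ in train_parts]
        quantifier, _ = m.train_quantifier(train_imgs, labels, cfg)
        preds = m.predict_count_batch(quantifier, test_imgs, count_max=count_max)

        fold_truth, fold_pred = [], []
        for (part, pp_), img, (norm, count) in zip(test_parts, test_imgs, preds):
            pred_grade = grade_from_count(count)
            rows.append(
                {
                    "subject_id": part.subject_id,
                    "slice_index": part.slice_index,
                    "hemisphere": part.hemisphere,
                    "fold": fold,
                    "truth_count": part.count,
                    "pred_count": count,
                    "truth_grade": part.grade,
                    "pred_grade": pred_grade,
                }
            )
            fold_truth.append(part.count)
            fold_pred.append(count)
            if part.count > 0 and pp_.mask.any():
                cnr_enh_all.append(part_cnr(img, pp_.mask, border=cnr_border).cnr)
                cnr_in_all.append(part_cnr(pp_.input_image, pp_.mask, border=cnr_border).cnr)
        per_fold_mae.append(mae(fold_truth, fold_pred))

    df = pd.DataFrame(rows)
    truth_counts = df.truth_count.to_numpy(float)
    pred_counts = df.pred_count.to_numpy(float)
    truth_grades = df.truth_grade.to_numpy(int)
    pred_grades = df.pred_grade.to_numpy(int)

    subj = df.groupby("subject_id").agg(truth=("truth_grade", "max"), pred=("pred_grade", "max"))
    icc_img = icc(truth_grades, pred_grades)
    icc_sub = icc(subj.truth.to_numpy(float), subj.pred.to_numpy(float))

    return EvalReport(
        method=method,
        k=k,
        seed=seed,
        count_max=count_max,
        pooled_mae=mae(truth_counts, pred_counts),
        pooled_mse=mse(truth_counts, pred_counts),
        image_accuracy=grade_accuracy(truth_grades, pred_grades),
        subject_accuracy=grade_accuracy(subj.truth.to_numpy(), subj.pred.to_numpy()),
        icc_image=icc_img,
        icc_subject=icc_sub,
        mean_cnr_enhanced=float(np.mean(cnr_enh_all)) if cnr_enh_all else float("nan"),
        mean_cnr_input=float(np.mean(cnr_in_all)) if cnr_in_all else float("nan"),
        per_fold_mae=per_fold_mae,
        n_images=len(df),
        n_subjects=len(prepared),
        predictions=df,
    )


# ---------------------------------------------------------------------------
# Cascade study driver
# ---------------------------------------------------------------------------

def run_cascade_study(
    n_subjects: int = 12,
    seed: int = 1,
    preset_name: str = "mini",
    out_shape=(40, 48),
    k: int = 4,
    cnr_border: int = 6,
) -> dict:
    """The package's end-to-end experiment at CPU scale: cross-validate the
    learned cascade against the non-enhanced route and the algorithmic
    baselines on one seeded phantom cohort.

    Returns a dict with mean CNR per enhancement method, pooled
    cross-validated MAE for the learned cascade and the non-enhanced route,
    the predict-the-training-mean reference MAE, and the accuracy/ICC block
    of the learned cascade.
    """
    from . import baseline_enhance as be
    from . import models as m
    from . import phantom as ph
    from . import preprocess as pp

    cohort = ph.generate_cohort(n_subjects, ph.desk_params(), seed=seed)
    cfg = m.preset(preset_name)

    report_dl = run_cross_validation(
        cohort, method="dl", train_config=cfg, k=k, seed=seed, out_shape=out_shape, cnr_border=cnr_border
    )
    report_none = run_cross_validation(
        cohort, method="none", train_config=cfg, k=k, seed=seed, out_shape=out_shape, cnr_border=cnr_border
    )

    # baseline CNR over the same parts the CV reports measure (count > 0 and
    # a nonempty resized mask)
    bcfg = be.BaselineConfig()
    baseline_fns = {
        "tophat": lambda im: be.tophat_enhance(im, bcfg.tophat_radius),
        "clahe": lambda im: be.clahe_enhance(im, bcfg.clahe_clip_limit, bcfg.clahe_tile_grid),
        "laplacian": lambda im: be.laplacian_enhance(im, bcfg.laplacian_weight),
    }
    cnr = {name: [] for name in baseline_fns}
    for rec in cohort:
        for part in rec.parts:
            prep = pp.prepare_part(part, out_shape=out_shape)
            if part.count > 0 and prep.mask.any():
                for name, fn in baseline_fns.items():
                    cnr[name].append(part_cnr(fn(prep.input_image), prep.mask, border=cnr_border).cnr)

    # predict-the-training-mean reference, pooled over the same folds
    plan = make_folds(sorted({r.subject_id for r in cohort}), k=k, seed=seed)
    counts = {r.subject_id: [p.count for p in r.parts] for r in cohort}
    truth_all, pred_all = [], []
    for fold in range(k):
        train_counts = [c for sid in plan.train_subjects(fold) for c in counts[sid]]
        mean_count = float(np.mean(train_counts))
        for sid in plan.test_subjects(fold):
            for c in counts[sid]:
                truth_all.append(c)
                pred_all.append(mean_count)

    return {
        "n_subjects": n_subjects,
        "seed": seed,
        "mean_cnr": {
            "none": report_dl.mean_cnr_input,
            "dl": report_dl.mean_cnr_enhanced,
            **{name: float(np.mean(v)) for name, v in cnr.items()},
        },
        "pooled_mae": {"dl": report_dl.pooled_mae, "none": report_none.pooled_mae},
        "predict_mean_mae": mae(truth_all, pred_all),
        "dl_report": report_dl,
        "none_report": report_none,
    }
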