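"""Self-validation experiments on the synthetic study conditions.

Each function runs one reproducible experiment against the package's own
synthetic ground truth and returns plain-dict metrics: end-to-end severity
recovery, attention localization, the class-imbalance diagnostic that
motivates focal-loss training, QC and stain-normalization effectiveness,
and brute-force oracle comparisons for the MIL algebra, the focal loss and
the agreement statistics.  The test suite asserts on these numbers and
``scripts/acceptance.py`` reports them; both therefore exercise exactly
the same code paths as a normal pipeline run.
"""

from __future__ import annotations

import itertools
import math
import tempfile
import time
from typing import Mapping

import numpy as np
from scipy import stats as sstats

from . import agreement, mil, preprocess, scoring, synthetic
from .cli import RunConfig, run_all

__all__ = [
    "endpoint_study",
    "imbalance_diagnostic",
    "preprocessing_checks",
    "statistics_oracle_errors",
    "mil_algebra_check",
    "focal_loss_check",
    "scoring_map_check",
]


# ---------------------------------------------------------------------------
# end-to-end synthetic recovery (neutrophils-in-epithelium, balanced)
# ---------------------------------------------------------------------------


def endpoint_study(
    seed: int = 7,
    n_biopsies: int = 200,
    image_size: int = 1024,
    out_dir: str | None = None,
) -> dict:
    """Full pipeline on the balanced binary neutrophil task.

    Generates ``n_biopsies`` biopsies (PolysEP severity 0 vs 2, balanced),
    runs every stage and returns held-out test accuracy, Cohen's kappa and
    the attention-localization fraction over positive test bags, plus the
    wall-clock runtime.
    """
    t0 = time.time()
    with tempfile.TemporaryDirectory() as tmp:
        config = RunConfig(
            seed=int(seed),
            out_dir=out_dir or tmp,
            n_biopsies=n_biopsies,
            image_size=image_size,
            severity_levels=(0, 2),
            majority_fraction=0.5,
        )
        result = run_all(config)
    result["runtime_s"] = round(time.time() - t0, 1)
    return result


def imbalance_diagnostic(
    seed: int = 7, n_biopsies: int = 120, image_size: int = 512
) -> dict:
    """Minority-class recall of FV+RF vs SA-AbMILP under 9:1 imbalance.

    Both aggregators share the embeddings and the stratified split, so the
    comparison isolates the aggregation/training strategy.  A random
    forest trained on Fisher vectors of a 9:1 skewed severity label tends
    to track the majority class; the attention model counters the skew
    with focal loss and inverse-frequency class weights.
    """
    from . import features

    ds = synthetic.generate_dataset(
        n_biopsies,
        {"PolysEP": {0: 0.5, 2: 0.5}},
        imbalance=0.9,
        image_size=image_size,
        seed=seed,
    )
    backbone = features.get_backbone(features.BackboneConfig(seed=seed))
    reference = None
    bags: dict[str, features.EmbeddingBag] = {}
    for i, row in ds.manifest.iterrows():
        img = ds.images[i]
        tm = preprocess.segment_tissue(img)
        patches = preprocess.tile_patches(
            img, tm, min_tissue=0.0, biopsy_id=row.biopsy_id
        )
        kept, _, _ = preprocess.qc_filter(patches, tissue_mask=tm)
        if not kept:
            continue
        if reference is None:
            reference = preprocess.fit_stain_reference(img)
        for p in kept:
            p.pixels, _ = preprocess.normalize_stain(p.pixels, reference)
        bags[row.biopsy_id] = features.embed_patches(kept, backbone=backbone)
    labels = dict(zip(ds.manifest.biopsy_id, ds.manifest.PolysEP.astype(int)))
    split = mil.split_dataset(ds.manifest, "PolysEP", seed=seed)

    def minority_recall(aggregator: str) -> float:
        config = mil.ModelConfig(
            aggregator=aggregator,
            class_weights="inverse" if aggregator == "sa_abmilp" else None,
        )
        model = mil.train(bags, labels, split, config, "colon", "PolysEP", seed=seed)
        minority = [b for b in split.testing_ids if b in bags and labels[b] == 2]
        hits = sum(mil.predict(model, bags[b])[0] == 2 for b in minority)
        return hits / len(minority) if minority else math.nan

    return {
        "fv_rf_minority_recall": minority_recall("fv_rf"),
        "sa_abmilp_minority_recall": minority_recall("sa_abmilp"),
        "majority_fraction": float((ds.manifest.PolysEP == 0).mean()),
    }


# ---------------------------------------------------------------------------
# preprocessing: tiling oracle, QC rates, stain normalization
# ---------------------------------------------------------------------------


def _tiling_agreement(rng: np.random.Generator, n_cases: int = 50) -> float:
    hits = 0
    for _ in range(n_cases):
        h = int(rng.integers(64, 400))
        w = int(rng.integers(64, 400))
        size = int(rng.integers(16, min(h, w) + 1))
        stride = int(rng.integers(1, size + 1))
        img = np.full((h, w, 3), 180, dtype=np.uint8)
        mask = preprocess.TissueMask(np.ones((h, w), dtype=bool))
        got = len(preprocess.tile_patches(img, mask, size, stride, min_tissue=0.0))
        expected = sum(
            1
            for r in range(0, h - size + 1, stride)
            for c in range(0, w - size + 1, stride)
        )
        hits += got == expected
    return hits / n_cases


def _qc_rates(seed: int) -> dict:
    artefact_total = artefact_rejected = 0
    clean_total = clean_rejected = 0
    for offset in range(6):
        spec = synthetic.SyntheticSpec(
            image_size=512,
            subgrade_severities={"PolysEP": 1},
            artefact_types=synthetic.ARTEFACT_TYPES,
            artefact_fraction=0.3,
            seed=seed + offset,
        )
        img, truth = synthetic.generate_biopsy(spec)
        tm = preprocess.segment_tissue(img)
        patches = preprocess.tile_patches(
            img, tm, 128, 64, min_tissue=0.0, biopsy_id="a"
        )
        kept, _, _ = preprocess.qc_filter(patches, tissue_mask=tm)
        kept_pos = {(p.row0, p.col0) for p in kept}
        for p in patches:
            overlap = truth.artefact_mask[
                p.row0 : p.row0 + p.size, p.col0 : p.col0 + p.size
            ].mean()
            if overlap >= 0.5:
                artefact_total += 1
                artefact_rejected += (p.row0, p.col0) not in kept_pos
    biopsy_seed = seed + 100
    while clean_total < 500:
        spec = synthetic.SyntheticSpec(
            image_size=512,
            subgrade_severities={"PolysEP": 2, "MonosLP": 1},
            seed=biopsy_seed,
        )
        img, _ = synthetic.generate_biopsy(spec)
        tm = preprocess.segment_tissue(img)
        patches = preprocess.tile_patches(
            img, tm, 224, 112, min_tissue=0.3, biopsy_id="c"
        )
        _, rejected, _ = preprocess.qc_filter(patches, tissue_mask=tm)
        clean_total += len(patches)
        clean_rejected += len(rejected)
        biopsy_seed += 1
    return {
        "artefact_patches": artefact_total,
        "artefact_rejection_rate": (
            artefact_rejected / artefact_total if artefact_total else math.nan
        ),
        "clean_patches": clean_total,
        "clean_false_rejection_rate": clean_rejected / clean_total,
    }


def _stain_variance_reduction(seed: int, n_copies: int = 100) -> dict:
    """Variance of foreground channel means across jittered copies of one
    biopsy, before and after Reinhard normalization to a common reference."""
    spec = synthetic.SyntheticSpec(
        image_size=512,
        subgrade_severities={"PolysEP": 2, "MonosLP": 1},
        stain_jitter=0.0,
        seed=seed,
    )
    base, _ = synthetic.generate_biopsy(spec)
    rng = np.random.default_rng(seed)
    reference = preprocess.fit_stain_reference(base)
    fg = ~(base >= preprocess.WHITE_THRESHOLD).all(axis=2)
    before, after = [], []
    for _ in range(n_copies):
        factors = synthetic.sample_stain_factors(rng, 0.2)
        jittered = synthetic.apply_stain_jitter(base, factors)
        normalized, _ = preprocess.normalize_stain(jittered, reference)
        before.append(jittered[fg].mean(axis=0))
        after.append(normalized[fg].mean(axis=0))
    var_before = np.var(np.stack(before), axis=0).mean()
    var_after = np.var(np.stack(after), axis=0).mean()
    return {
        "channel_mean_variance_before": float(var_before),
        "channel_mean_variance_after": float(var_after),
        "variance_reduction": float(1.0 - var_after / var_before),
    }


def preprocessing_checks(seed: int = 7) -> dict:
    rng = np.random.default_rng(seed)
    out = {"tiling_oracle_agreement": _tiling_agreement(rng)}
    out.update(_qc_rates(seed))
    out.update(_stain_variance_reduction(seed))
    return out


# ---------------------------------------------------------------------------
# statistics: direct-formula oracle comparison
# ---------------------------------------------------------------------------


def statistics_oracle_errors(seed: int = 7, n_fuzz: int = 500) -> dict:
    """Max absolute deviation of each statistic from a direct-formula
    recomputation over fuzzed inputs, plus the hand-worked examples."""
    rng = np.random.default_rng(seed)
    err_cohen = err_fleiss = err_z = err_or = 0.0
    for _ in range(n_fuzz):
        # Cohen's kappa
        n = int(rng.integers(4, 60))
        ref = rng.integers(0, 3, n)
        pred = rng.integers(0, 3, n)
        labels = sorted(set(ref) | set(pred))
        C = np.zeros((len(labels), len(labels)))
        for r, p in zip(ref, pred):
            C[labels.index(r), labels.index(p)] += 1
        po = np.trace(C) / n
        pe = float(C.sum(1) @ C.sum(0)) / n**2
        if pe < 1.0:
            err_cohen = max(
                err_cohen,
                abs(
                    agreement.cohen_kappa(ref.tolist(), pred.tolist())
                    - (po - pe) / (1 - pe)
                ),
            )
        # Fleiss' kappa
        items, raters = int(rng.integers(3, 15)), int(rng.integers(2, 6))
        ratings = rng.integers(0, 3, (items, raters)).astype(float)
        cats = np.unique(ratings)
        if cats.size >= 2:
            counts = np.stack([(ratings == c).sum(1) for c in cats], 1)
            pi = np.sum(counts * (counts - 1), 1) / (raters * (raters - 1))
            pj = counts.sum(0) / counts.sum()
            pe = float(np.sum(pj**2))
            expected = (pi.mean() - pe) / (1 - pe)
            got = agreement.fleiss_kappa(agreement.PanelScores(ratings))
            err_fleiss = max(err_fleiss, abs(got - expected))
        # two-proportion Z
        n1, n2 = (int(x) for x in rng.integers(5, 200, 2))
        s1, s2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
        pooled = (s1 + s2) / (n1 + n2)
        if 0.0 < pooled < 1.0:
            se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            z_expected = (s1 / n1 - s2 / n2) / se
            res = agreement.two_proportion_z(s1, n1, s2, n2)
            err_z = max(err_z, abs(res.z - z_expected))
            err_z = max(err_z, abs(res.p_value - 2 * sstats.norm.sf(abs(z_expected))))
        # odds ratio + Woolf CI
        a, b, c, d = (int(x) for x in rng.integers(1, 40, 4))
        res = agreement.odds_ratio_ci([[a, b], [c, d]])
        expected_or = a * d / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        zc = sstats.norm.ppf(0.975)
        err_or = max(err_or, abs(res.odds_ratio - expected_or))
        err_or = max(
            err_or, abs(res.ci_low - math.exp(math.log(expected_or) - zc * se))
        )
    # hand-worked examples
    ref, pred = [], []
    for i, row in enumerate([[40, 10], [5, 45]]):
        for j, cnt in enumerate(row):
            ref += [i] * cnt
            pred += [j] * cnt
    hand = {
        "hand_cohen_kappa": agreement.cohen_kappa(ref, pred),
        "hand_fleiss_kappa": agreement.fleiss_kappa(
            agreement.PanelScores(np.array([[0, 0, 0], [1, 1, 1], [0, 0, 1]]))
        ),
        "hand_two_proportion_z": agreement.two_proportion_z(74, 100, 93, 100).z,
        "hand_odds_ratio": agreement.odds_ratio_ci([[20, 5], [10, 40]]).odds_ratio,
    }
    return {
        "n_fuzz": n_fuzz,
        "max_error_cohen_kappa": err_cohen,
        "max_error_fleiss_kappa": err_fleiss,
        "max_error_two_proportion_z": err_z,
        "max_error_odds_ratio": err_or,
        **hand,
    }


# ---------------------------------------------------------------------------
# MIL algebra and focal loss oracles
# ---------------------------------------------------------------------------


def mil_algebra_check(seed: int = 7, n_bags: int = 1000) -> dict:
    """Fuzz the attention-pooling invariants over random bags and weights."""
    rng = np.random.default_rng(seed)
    models = []
    for s in range(4):
        config = mil.ModelConfig(
            n_classes=2,
            attention_hidden=8,
            self_attention=bool(s % 2),
            gated=bool((s // 2) % 2),
        )
        m = mil.SAAbMILP(16, config, seed=seed + s)
        if config.self_attention:
            m.params["g"] = np.array(0.4)
        models.append(m)
    max_sum_dev = max_perm_dev = max_rep_dev = max_single_dev = max_dup_dev = 0.0
    for i in range(n_bags):
        m = models[i % len(models)]
        n = int(rng.integers(1, 12))
        H = rng.standard_normal((n, 16)) * float(rng.uniform(0.3, 3.0))
        out = m.forward(H)
        max_sum_dev = max(max_sum_dev, abs(float(out.a.sum()) - 1.0))
        perm = rng.permutation(n)
        out_p = m.forward(H[perm])
        max_perm_dev = max(max_perm_dev, float(np.abs(out_p.z - out.z).max()))
        rep = m.forward(np.repeat(H, 3, axis=0))
        max_rep_dev = max(max_rep_dev, float(np.abs(rep.z - out.z).max()))
        single = m.forward(H[:1])
        max_single_dev = max(max_single_dev, abs(float(single.a[0]) - 1.0))
        dup = m.forward(np.stack([H[0], H[0]]))
        max_dup_dev = max(max_dup_dev, float(np.abs(dup.a - 0.5).max()))
    return {
        "n_bags": n_bags,
        "max_attention_sum_deviation": max_sum_dev,
        "max_permutation_z_deviation": max_perm_dev,
        "max_replication_z_deviation": max_rep_dev,
        "max_single_instance_deviation": max_single_dev,
        "max_duplicate_symmetry_deviation": max_dup_dev,
    }


def focal_loss_check(seed: int = 7, n_fuzz: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    max_ce_dev = 0.0
    for _ in range(n_fuzz):
        c = int(rng.integers(2, 6))
        logits = rng.standard_normal(c) * 3.0
        y = int(rng.integers(c))
        p = np.exp(logits - logits.max())
        p /= p.sum()
        ce = -math.log(p[y])
        max_ce_dev = max(max_ce_dev, abs(mil.focal_loss(logits, y, gamma=0.0) - ce))
    hand = mil.focal_loss(np.array([0.1, 0.9]), 1, gamma=2.0, scores_are_probs=True)
    zero = mil.focal_loss(np.array([0.0, 1.0]), 1, gamma=2.0, scores_are_probs=True)
    return {
        "n_fuzz": n_fuzz,
        "max_gamma0_vs_cross_entropy": max_ce_dev,
        "loss_at_pt_1": zero,
        "hand_value_gamma2_pt09": hand,
    }


# ---------------------------------------------------------------------------
# scoring maps
# ---------------------------------------------------------------------------


def scoring_map_check() -> dict:
    """Enumerate the full GHAS and Geboes score spaces against the
    presence-of-pathology lookup rules; check simplify-Geboes laws."""
    rules: dict[scoring.System, Mapping[scoring.PathologyFeature, str]] = {
        scoring.System.GHAS: {
            scoring.PathologyFeature.EPITHELIUM_DAMAGE: "EPDAM",
            scoring.PathologyFeature.NEUTROPHILS_EPITHELIUM: "PolysEP",
            scoring.PathologyFeature.NEUTROPHILS_LAMINA_PROPRIA: "PolysLP",
            scoring.PathologyFeature.MONONUCLEAR_OR_CHRONIC_INFLAMMATION: "MonosLP",
        },
        scoring.System.GEBOES: {
            scoring.PathologyFeature.EPITHELIUM_DAMAGE: "G5",
            scoring.PathologyFeature.NEUTROPHILS_EPITHELIUM: "G3",
            scoring.PathologyFeature.NEUTROPHILS_LAMINA_PROPRIA: "G2B",
            scoring.PathologyFeature.MONONUCLEAR_OR_CHRONIC_INFLAMMATION: "G1",
        },
    }
    out = {}
    for system, rule in rules.items():
        subgrades = scoring.subgrades_for(system)
        states = mismatches = 0
        for combo in itertools.product(range(4), repeat=len(subgrades)):
            score = scoring.ScoreSet(
                system=system,
                compartment=scoring.Compartment.COLON,
                severities=dict(zip(subgrades, combo)),
            )
            states += 1
            for feature, subgrade in rule.items():
                if scoring.binarize(score, feature).present != (score[subgrade] > 0):
                    mismatches += 1
        out[f"{system.value.lower()}_states"] = states
        out[f"{system.value.lower()}_binarize_mismatches"] = mismatches
    # simplify-Geboes: idempotent and order-preserving over all levels
    violations = 0
    for grade in scoring.GEBOES_GRADES:
        mapped = []
        for sev in range(4):
            score = scoring.ScoreSet(
                scoring.System.GEBOES, scoring.Compartment.COLON, {grade: sev}
            )
            simplified = scoring.simplify_geboes(score)
            twice = scoring.simplify_geboes(simplified)
            if twice.severities != simplified.severities:
                violations += 1
            if simplified[grade] > sev:
                violations += 1
            mapped.append(simplified[grade])
        if mapped != sorted(mapped):
            violations += 1
    out["simplify_geboes_violations"] = violations
    return out
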