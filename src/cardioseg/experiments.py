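"""Desk-scale reference experiments.

:func:`ssl_comparison` is the package's end-to-end study in miniature: it
builds patient-structured phantom splits with a small labeled fraction,
trains selected method variants over several seeds, and evaluates mean
test DSC/ASSD per variant.  The qualitative claim under test is that
semi-supervised training improves on the low-label supervised baseline
(SV < STTC <= STTC-PL-STTC on seed-averaged means).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np

from . import network
from .cascade import run_variant
from .metrics import evaluate_prediction
from .phantom import PhantomConfig, generate_split
from .presets import PROFILES, Profile

__all__ = ["ssl_comparison"]


def _evaluate(model, test_pairs):
    dscs, assds = [], []
    for img, lab in test_pairs:
        rep = evaluate_prediction(network.predict(model, img), lab,
                                  img.spacing)
        dscs.append(rep.mean_dsc)
        assds.append(rep.mean_assd)
    return float(np.mean(dscs)), float(np.nanmean(assds))


def ssl_comparison(master_seed: int, n_seeds: int = 3,
                   variants: Iterable[str] = ("SV", "STTC", "STTC-PL-STTC"),
                   profile: Optional[Profile] = None,
                   n_total: int = 200, labeled_fraction: float = 0.05,
                   n_test: int = 20, progress=None) -> Dict[str, dict]:
    """Seed-averaged test DSC/ASSD per method variant.

    Each seed derives an independent (data, training) seed pair from
    ``master_seed``; all variants of one seed share the same split and
    training seed, so the strategy comparison is paired.  Returns
    ``{variant: {"dsc": mean, "assd": mean, "per_seed_dsc": [...]}}``.
    """
    profile = profile or PROFILES["desk2d"]
    out: Dict[str, dict] = {v: {"per_seed_dsc": [], "per_seed_assd": []}
                            for v in variants}
    for s in range(n_seeds):
        ss = np.random.SeedSequence([master_seed, s])
        data_seed, train_seed = [int(x & 0x7FFFFFFF)
                                 for x in ss.generate_state(2)]
        cfg = PhantomConfig(dim=profile.dim, grid=profile.target_shape,
                            num_classes=profile.num_classes)
        split, test_pairs = generate_split(
            cfg, n_total=n_total, labeled_fraction=labeled_fraction,
            seed=data_seed, n_test=n_test)
        for variant in variants:
            result = run_variant(variant, split, profile.schedule(),
                                 train_seed, dim=profile.dim,
                                 base_channels=profile.base_channels,
                                 lr_overrides=profile.lr_overrides())
            dsc, assd = _evaluate(result.final_model, test_pairs)
            out[variant]["per_seed_dsc"].append(dsc)
            out[variant]["per_seed_assd"].append(assd)
            if progress is not None:
                progress(seed=s, variant=variant, dsc=dsc, assd=assd)
    for v in variants:
        out[v]["dsc"] = float(np.mean(out[v]["per_seed_dsc"]))
        out[v]["assd"] = float(np.mean(out[v]["per_seed_assd"]))
    return out
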