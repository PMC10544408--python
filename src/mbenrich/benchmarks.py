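"""End-to-end benchmark pipeline: simulate, train, cross-validate, score.

Presets reproduce the structure of the full-scale selection-experiment
grid at laptop scale: the library construction, epistasis scaling
(T = 20 L_a), read mode and pre/post balance are preserved while absolute
library and read counts are reduced so a complete three-fold
cross-validation of both estimators runs in minutes on one CPU.

The cross-validation is sequence-level and scored against the simulated
ground-truth fitness: for each fold, models are trained on the reads of
the training-fold sequences and evaluated by Spearman correlation between
their predictions on held-out unique sequences and those sequences' true
fitness values (an oracle unavailable in real experiments, which is the
point of simulating).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .counts import compute_cle
from .evaluation import make_folds
from .fitness import default_T, simulate_fitness
from .mbe import fit_mbe
from .simulate import (Library, mutagenesis_library, nnk_library, random_parents,
                       recombination_library, sample_reads, simulate_selection)
from .wler import build_wler_training_set, fit_wler
from .zoo import ModelConfig, TrainConfig

#: Scaled-down study conditions. Each preserves its full-scale template's
#: construction, T-scaling, read mode and equal pre/post depths.
PRESETS = {
    # NNK 21-mer insertion: full scale 8.5e6 unique / 4.6e7 reads; here
    # 5e4 unique / 5e5 reads (reads cover the whole insert).
    "insertion-21mer": dict(
        library="nnk", n_codons=7, target_unique=50_000, T=140,
        read_mode="full", N=500_000,
    ),
    # small smoke-test variant of the same construction
    "insertion-21mer-small": dict(
        library="nnk", n_codons=7, target_unique=2_000, T=140,
        read_mode="full", N=20_000,
    ),
    # avGFP-style random mutagenesis, long reads (scaled from 238 aa /
    # 2.5e7 unique / 4.6e5 reads)
    "mutagenesis-small": dict(
        library="mutagenesis", n_codons=60, per_site_rate=0.01,
        target_unique=4_000, T=default_T(60), read_mode="full", N=4_000,
    ),
    # AAV-style recombination, sparse long reads: 9 synthetic parents,
    # 8 blocks; read depth an order of magnitude below the unique count.
    "recombination-sparse": dict(
        library="recombination", n_parents=9, n_blocks=8, n_codons=78,
        target_unique=4_000, T=default_T(78), read_mode="full", N=800,
    ),
    # short-read variant of the recombination library (codon-aligned
    # 26-codon windows ~ 1/3 coverage)
    "recombination-short": dict(
        library="recombination", n_parents=9, n_blocks=8, n_codons=78,
        target_unique=4_000, T=default_T(78), read_mode="short",
        window_codons=26, N=40_000,
    ),
}


@dataclass
class SimulationBundle:
    """One simulated experiment: library, truth, distributions, reads."""

    library: Library
    fitness: object
    selection: object
    readset: object
    aa_sequences: list
    aa_fitness: np.ndarray


def simulate_preset(name: str, seed: int = 0) -> SimulationBundle:
    """Materialize a preset with all randomness derived from ``seed``."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    p = PRESETS[name]
    root = np.random.SeedSequence([seed, zlib.crc32(name.encode()) % (2 ** 31)])
    r_lib, r_fit, r_sel, r_reads = [np.random.default_rng(s)
                                    for s in root.spawn(4)]
    if p["library"] == "nnk":
        lib = nnk_library(p["n_codons"], p["target_unique"], r_lib)
    elif p["library"] == "mutagenesis":
        ref = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                      for i in r_lib.integers(0, 20, size=p["n_codons"]))
        lib = mutagenesis_library(ref, p["per_site_rate"], p["target_unique"], r_lib)
    elif p["library"] == "recombination":
        parents = random_parents(p["n_parents"], p["n_codons"], r_lib)
        lib = recombination_library(parents, p["n_blocks"], rng=r_lib,
                                    target_unique=p["target_unique"])
    else:
        raise ValueError(p["library"])
    L_a = len(lib.sequences[0]) // 3
    fit = simulate_fitness(L_a, T=p["T"], seed=int(r_fit.integers(2 ** 31)))
    sel = simulate_selection(lib, fit, r_sel)
    readset = sample_reads(sel, p["N"], p["N"], read_mode=p["read_mode"],
                           window_codons=p.get("window_codons", 100),
                           rng=r_reads, error_rate=p.get("error_rate", 0.0))
    aa = lib.translated()
    # distinct nucleotide sequences can share a translation; evaluation
    # units are unique amino-acid sequences
    uniq = list(dict.fromkeys(aa))
    return SimulationBundle(lib, fit, sel, readset, uniq, fit.evaluate(uniq))


@dataclass
class CVResult:
    spearman_mbe: float | None
    spearman_wler: float | None
    spearman_cle: float | None
    per_fold_mbe: list = field(default_factory=list)
    per_fold_wler: list = field(default_factory=list)


def crossval_compare(bundle: SimulationBundle, seed: int = 0, k: int = 3,
                     arch: str = "fcn", hidden_units: int = 100,
                     conv_layers: int = 8, methods=("mbe", "wler"),
                     train_config: TrainConfig | None = None) -> CVResult:
    """Sequence-level k-fold CV of MBE and wLER against true fitness.

    Training folds see only the reads of their sequences; predictions are
    made on the held-out unique amino-acid sequences and scored by
    Spearman correlation with ground-truth fitness, averaged over folds.
    Also reports the estimation-only cLE Spearman over observed test
    sequences when reads cover the full sequence of interest.

    The default batch size is 128 rather than the 1024 used at full scale:
    under the fixed ten-epoch recipe, the optimizer step count — not the
    epoch count — is what full-scale training actually provides, and the
    presets are ~200x smaller. The choice applies identically to both
    estimators.
    """
    if train_config is None:
        train_config = TrainConfig(batch_size=128)
    table = bundle.readset.to_count_table()
    folds = make_folds(bundle.aa_sequences, k=k, seed=seed)
    truth = {s: f for s, f in zip(bundle.aa_sequences, bundle.aa_fitness)}
    # every read follows its source library sequence's fold (reads of
    # held-out sequences, truncated or not, never reach training data)
    lib_aa = bundle.library.translated()
    per_mbe, per_wler, per_cle = [], [], []
    for f in range(k):
        test_seqs = [folds.sequences[i] for i in folds.test_indices(f)]
        test_set = set(test_seqs)
        train_sources = [i for i, a in enumerate(lib_aa) if a not in test_set]
        sub = bundle.readset.to_count_table(sources=train_sources)
        if (sub.totals == 0).any():
            # under strong selection all of one condition's reads can come
            # from held-out sequences; such a fold carries no training
            # signal for either estimator and is skipped for both
            continue
        y_true = np.array([truth[s] for s in test_seqs])
        if "mbe" in methods:
            cfg = _model_config(arch, hidden_units, conv_layers,
                                "classification", sub.n_conditions, seed + f)
            drm = fit_mbe(sub, model_config=cfg, train_config=train_config,
                          seed=seed + f)
            pred = drm.predict_log_enrichment(test_seqs)
            per_mbe.append(float(stats.spearmanr(pred, y_true).statistic))
        if "wler" in methods:
            cfg = _model_config(arch, hidden_units, conv_layers,
                                "regression", 1, seed + f)
            tset = build_wler_training_set(sub)
            model = fit_wler(tset, model_config=cfg, train_config=train_config,
                             seed=seed + f)
            pred = model.predict(test_seqs)[:, 0]
            per_wler.append(float(stats.spearmanr(pred, y_true).statistic))
        if "cle" in methods:
            obs = [s for s in test_seqs if s in set(table.sequences)]
            if len(obs) >= 3:
                est = compute_cle(table)
                cle_map = dict(zip(table.sequences, est.log_e))
                per_cle.append(float(stats.spearmanr(
                    [cle_map[s] for s in obs],
                    [truth[s] for s in obs]).statistic))
    return CVResult(
        spearman_mbe=float(np.mean(per_mbe)) if per_mbe else None,
        spearman_wler=float(np.mean(per_wler)) if per_wler else None,
        spearman_cle=float(np.mean(per_cle)) if per_cle else None,
        per_fold_mbe=per_mbe, per_fold_wler=per_wler,
    )


def _model_config(arch, hidden_units, conv_layers, head, n_outputs, seed):
    if arch == "fcn":
        return ModelConfig("fcn", hidden_units=hidden_units, head=head,
                           n_outputs=n_outputs, seed=seed)
    if arch == "cnn":
        return ModelConfig("cnn", conv_layers=conv_layers, head=head,
                           n_outputs=n_outputs, seed=seed)
    return ModelConfig(arch, head=head, n_outputs=n_outputs, seed=seed)


def run_preset(name: str, seed: int = 0, **cv_kwargs) -> CVResult:
    """Simulate a preset and cross-validate the estimators on it."""
    bundle = simulate_preset(name, seed=seed)
    return crossval_compare(bundle, seed=seed, **cv_kwargs)
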