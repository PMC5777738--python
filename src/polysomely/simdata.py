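"""Synthetic polysome-profiling experiments with planted regulation.

The generator emulates the design of a polysome-profiling RNA-seq screen:
cell lines x treatments (normoxia control N, hypoxia H, mTOR inhibition PP,
both HPP) x two RNA pools per sample — total RNA (T) and polysome-bound RNA
(P) — with replicate libraries. Every gene carries a known regulation class:

* ``null`` — no effect in either pool;
* ``transcriptional`` — a log2 shift t shared by both pools (mRNA level
  changes, translation follows);
* ``translational`` — a log2 shift d in the polysomal pool only (ribosome
  loading changes at constant mRNA);
* ``buffered`` — a transcriptional shift t compensated translationally
  (d = -t), so polysomal abundance stays flat while total moves.

Counts follow a negative binomial (Gamma-Poisson) with variance
mean + phi * mean^2; phi = 0 samples Poisson exactly. Expected proportions
are renormalized per sample before sampling, because sequencing measures
relative, not absolute, abundance; with regulated fractions kept modest
(<= 20%) the compositional distortion of planted effects is second-order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, SampleDesign

__all__ = ["SimConfig", "SimTruth", "SimExperiment", "SimConfigError", "simulate_experiment"]

CLASSES = ("null", "transcriptional", "translational", "buffered")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults mirror the screen being emulated: two breast cell lines, four
    treatments with normoxia first (the control), total + polysomal pools,
    and two replicate libraries per (cell line x treatment x pool). Replicate
    count and sequencing depth are generator choices, not study facts.
    """

    n_genes: int = 5000
    cell_lines: tuple[str, ...] = ("MCF10A", "MDA-MB-231")
    treatments: tuple[str, ...] = ("N", "H", "PP", "HPP")  # control first
    replicates: int = 2
    class_proportions: dict = field(
        default_factory=lambda: {
            "null": 0.85,
            "transcriptional": 0.05,
            "translational": 0.05,
            "buffered": 0.05,
        }
    )
    effect_size_log2: float = 1.0
    baseline_log_mean: float = 4.0   # natural-log scale of mean relative abundance
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    dispersion_trend: tuple[float, float] | None = None  # (phi0, phi1): phi0 + phi1/mean
    polysome_loading_logit_sd: float = 0.7
    library_size_mean: float = 1.5e6
    library_size_cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.replicates < 2:
            raise SimConfigError("replicates must be >= 2")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if len(self.treatments) < 2:
            raise SimConfigError("treatments needs a control plus >= 1 condition")
        props = self.class_proportions
        unknown = set(props) - set(CLASSES)
        if unknown:
            raise SimConfigError(f"class_proportions has unknown classes {sorted(unknown)}")
        vals = [props.get(c, 0.0) for c in CLASSES]
        if any(v < 0 for v in vals):
            raise SimConfigError("class_proportions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise SimConfigError(f"class_proportions must sum to 1, got {sum(vals)}")
        if self.effect_size_log2 <= 0:
            raise SimConfigError("effect_size_log2 must be positive")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise SimConfigError("library size parameters must be positive / non-negative")

    @property
    def control(self) -> str:
        return self.treatments[0]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth regulation per gene.

    ``table`` columns: gene_id, gene_class, then t_<treatment> and
    d_<treatment> log2 effects for every non-control treatment.
    """

    table: pd.DataFrame
    treatments: tuple[str, ...]

    def labels(self) -> pd.Series:
        return self.table.set_index("gene_id")["gene_class"]


@dataclass(frozen=True)
class SimExperiment:
    counts: CountMatrix
    design: SampleDesign
    truth: SimTruth
    config: SimConfig


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB draw with variance mean + phi*mean^2; Poisson at phi=0."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, mean[~pois] * phi[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_experiment(config: SimConfig) -> SimExperiment:
    """Draw one complete experiment from the generative model.

    Per gene g: relative abundance a_g ~ LogNormal(baseline_log_mean,
    baseline_log_sd); polysome-loading fraction r_g = sigmoid(eta_g) with
    eta_g ~ Normal(0, polysome_loading_logit_sd). For treatment c the
    expected proportion in the total pool is proportional to a_g * 2^t_gc and
    in the polysomal pool to a_g * r_g * 2^(t_gc + d_gc); each pool's vector
    is renormalized to sum 1 per sample before NB sampling at the sample's
    library size. The same config (seed included) is bit-reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    # class assignment by iid draw from the configured proportions
    probs = np.array([config.class_proportions.get(c, 0.0) for c in CLASSES])
    cls = rng.choice(len(CLASSES), size=n, p=probs)
    labels = np.array(CLASSES, dtype=object)[cls]

    non_control = [t for t in config.treatments if t != config.control]
    t_eff = {t: np.zeros(n) for t in non_control}
    d_eff = {t: np.zeros(n) for t in non_control}
    for t in non_control:
        sign = rng.choice([-1.0, 1.0], size=n)
        mag = config.effect_size_log2 * sign
        is_tx = labels == "transcriptional"
        is_tl = labels == "translational"
        is_bf = labels == "buffered"
        t_eff[t][is_tx] = mag[is_tx]
        d_eff[t][is_tl] = mag[is_tl]
        t_eff[t][is_bf] = mag[is_bf]
        d_eff[t][is_bf] = -mag[is_bf]

    a = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    eta = rng.normal(0.0, config.polysome_loading_logit_sd, size=n)
    r = 1.0 / (1.0 + np.exp(-eta))

    # per-gene dispersion: scalar or mean-dependent trend phi0 + phi1/mean
    def gene_phi(mean_per_gene: np.ndarray) -> np.ndarray:
        if config.dispersion_trend is None:
            return np.full(n, config.dispersion)
        phi0, phi1 = config.dispersion_trend
        return phi0 + phi1 / np.maximum(mean_per_gene, 1.0)

    rows = []
    columns: dict[str, np.ndarray] = {}
    for cell in config.cell_lines:
        for treat in config.treatments:
            t_vec = t_eff.get(treat, np.zeros(n)) if treat != config.control else np.zeros(n)
            d_vec = d_eff.get(treat, np.zeros(n)) if treat != config.control else np.zeros(n)
            q_t = a * 2.0 ** t_vec
            q_p = a * r * 2.0 ** (t_vec + d_vec)
            q_t = q_t / q_t.sum()
            q_p = q_p / q_p.sum()
            for pool, q in (("T", q_t), ("P", q_p)):
                for rep in range(1, config.replicates + 1):
                    lib = rng.normal(
                        config.library_size_mean,
                        config.library_size_cv * config.library_size_mean,
                    )
                    lib = max(lib, 0.05 * config.library_size_mean)
                    mean = lib * q
                    counts = _nb_sample(rng, mean, gene_phi(mean))
                    sid = f"{cell}_{treat}_{pool}_{rep}"
                    columns[sid] = counts
                    rows.append(
                        {
                            "sample_id": sid,
                            "cell_line": cell,
                            "treatment": treat,
                            "pool": pool,
                            "replicate": rep,
                        }
                    )

    counts_df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    truth_df = pd.DataFrame({"gene_id": gene_ids, "gene_class": labels})
    for t in non_control:
        truth_df[f"t_{t}"] = t_eff[t]
        truth_df[f"d_{t}"] = d_eff[t]
    return SimExperiment(
        counts=CountMatrix(counts_df),
        design=SampleDesign(pd.DataFrame(rows)),
        truth=SimTruth(truth_df, tuple(non_control)),
        config=config,
    )
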