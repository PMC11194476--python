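"""Synthetic multi-omics generator with known subtype structure.

Samples carry a latent factor vector (subtype centroid + unit Gaussian);
each genomics view and the protein matrix are linear maps of the latent
factors plus Gaussian noise, so the genomics-to-protein translation is
representable and recovery is provable. Protein availability is masked
uniformly at random at rate 1 - theta; survival times are exponential
with per-subtype hazards and uniform censoring; one discrete clinical
column tracks the subtype (with flips) and one continuous column is
independent noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datamodel import ClinicalTable, MultiOmicsDataset, OmicsMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_dataset", "sweep_missing_rates"]


@dataclasses.dataclass
class SyntheticConfig:
    """Generator settings; defaults are the package's reference conditions."""

    n_samples: int = 150
    n_subtypes: int = 3
    latent_dim: int = 5
    view_dims: tuple[int, ...] = (100, 80)
    protein_dim: int = 20
    view_noise_sd: float = 0.5
    protein_noise_sd: float = 0.1
    cluster_separation: float = 8.0  # expected centroid pairwise distance
    missing_rate: float = 0.2  # theta: fraction of samples lacking protein
    survival_hazards: tuple[float, ...] | None = None  # per-subtype exp rates
    censor_rate: float = 0.2
    clinical_flip_rate: float = 0.1
    nonlinear_protein: bool = False  # elementwise tanh on the protein map

    def __post_init__(self) -> None:
        if self.n_samples < self.n_subtypes:
            raise ValueError("need at least one sample per subtype")
        if min(self.view_dims) < 1 or self.protein_dim < 1:
            raise ValueError("view and protein dimensions must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.survival_hazards is not None and len(self.survival_hazards) != self.n_subtypes:
            raise ValueError("one survival hazard per subtype is required")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset."""

    true_labels: np.ndarray  # subtype per sample, 1..k
    latent: np.ndarray  # n x latent_dim factor matrix
    view_loadings: list[np.ndarray]
    protein_loadings: np.ndarray
    protein_full: np.ndarray  # noisy protein for ALL samples, pre-masking


def _default_hazards(k: int) -> np.ndarray:
    # geometric spacing: clearly different prognoses between subtypes
    return 0.01 * 2.0 ** np.arange(k)


def _simplex_centroids(rng: np.random.Generator, k: int, d: int, separation: float) -> np.ndarray:
    """k centroids in R^d at exact pairwise distance `separation`.

    Vertices of a regular (k-1)-simplex centered at the origin, embedded
    in the first k-1 coordinates and randomly rotated (Haar via QR).
    Requires d >= k - 1 so the simplex fits.
    """
    if d < k - 1:
        raise ValueError(f"latent_dim={d} too small for {k} equidistant centroids")
    # vertices of the regular simplex from centered identity columns
    V = np.eye(k) - 1.0 / k  # k points in R^k, pairwise distance sqrt(2)
    # orthonormal basis of the (k-1)-dim affine span
    Q, _ = np.linalg.qr(V.T[:, : k - 1])
    pts = V @ Q  # k x (k-1), pairwise distance sqrt(2)
    pts = pts * (separation / np.sqrt(2.0))
    embedded = np.zeros((k, d))
    embedded[:, : k - 1] = pts
    G = rng.standard_normal((d, d))
    R, _ = np.linalg.qr(G)
    return embedded @ R.T


def simulate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[MultiOmicsDataset, ClinicalTable, SyntheticTruth]:
    """Simulate an aligned multi-omics dataset with known subtypes."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n, k, d = config.n_samples, config.n_subtypes, config.latent_dim

    centroids = _simplex_centroids(rng, k, d, config.cluster_separation)

    # round-robin subtype assignment, then shuffled: all subtypes nonempty
    labels = np.tile(np.arange(1, k + 1), n // k + 1)[:n]
    rng.shuffle(labels)
    latent = centroids[labels - 1] + rng.standard_normal((n, d))

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    views = []
    view_loadings = []
    for v, dv in enumerate(config.view_dims):
        loadings = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, dv))
        X = latent @ loadings + rng.normal(0.0, config.view_noise_sd, size=(n, dv))
        views.append(
            OmicsMatrix(
                f"view{v + 1}", sample_ids,
                [f"v{v + 1}_f{j + 1}" for j in range(dv)], X,
            )
        )
        view_loadings.append(loadings)

    protein_loadings = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, config.protein_dim))
    signal = latent @ protein_loadings
    if config.nonlinear_protein:
        signal = np.tanh(signal)
    protein_values = signal + rng.normal(
        0.0, config.protein_noise_sd, size=(n, config.protein_dim)
    )
    n_missing = int(np.ceil(config.missing_rate * n))
    mask = np.ones(n, dtype=bool)
    if n_missing > 0:
        mask[rng.choice(n, size=n_missing, replace=False)] = False
    protein_stored = protein_values * mask[:, None]  # placeholders zeroed
    protein = OmicsMatrix(
        "protein", sample_ids,
        [f"p{j + 1}" for j in range(config.protein_dim)], protein_stored,
    )
    dataset = MultiOmicsDataset(views=views, protein=protein, protein_mask=mask)

    hazards = (
        np.asarray(config.survival_hazards, dtype=np.float64)
        if config.survival_hazards is not None
        else _default_hazards(k)
    )
    times = rng.exponential(1.0 / hazards[labels - 1])
    events = np.ones(n, dtype=bool)
    censored = rng.random(n) < config.censor_rate
    times = np.where(censored, times * rng.random(n), times)
    events[censored] = False

    flip = rng.random(n) < config.clinical_flip_rate
    noisy_subtype = np.where(flip, rng.integers(1, k + 1, size=n), labels)
    params = pd.DataFrame(
        {
            "subtype_marker": [f"grade{g}" for g in noisy_subtype],
            "noise_covariate": rng.standard_normal(n),
        }
    )
    clinical = ClinicalTable(
        sample_ids=sample_ids,
        survival_time=times,
        event=events,
        parameters=params,
        types={"subtype_marker": "discrete", "noise_covariate": "continuous"},
    )
    truth = SyntheticTruth(
        true_labels=labels,
        latent=latent,
        view_loadings=view_loadings,
        protein_loadings=protein_loadings,
        protein_full=protein_values,
    )
    return dataset, clinical, truth


def sweep_missing_rates(
    base_config: SyntheticConfig,
    thetas,
    seeds,
    translation_config=None,
    clustering_config=None,
) -> pd.DataFrame:
    """Run the full pipeline per (theta, seed); return (theta, seed, ARI) rows.

    The ARI compares the pipeline's final labels with the generator's true
    subtypes, replicating the missing-rate robustness design at desk scale.
    """
    from .evaluation import adjusted_rand_index
    from .pipeline import run_from_dataset

    rows = []
    for theta in thetas:
        if not 0 <= theta < 1:
            raise ValueError("each theta must be in [0, 1)")
        cfg = dataclasses.replace(base_config, missing_rate=float(theta))
        for seed in seeds:
            dataset, _, truth = simulate_dataset(cfg, seed=int(seed))
            result = run_from_dataset(
                dataset,
                n_clusters=cfg.n_subtypes,
                translation_config=translation_config,
                clustering_config=clustering_config,
                seed=int(seed),
            )
            ari = adjusted_rand_index(result.cluster_result.labels, truth.true_labels)
            rows.append({"theta": float(theta), "seed": int(seed), "ari": ari})
    return pd.DataFrame(rows)
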