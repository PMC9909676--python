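"""Fragment-probability models: a message-passing GNN with two heads.

Both heads share the same backbone: per-atom input features and the
bond-order adjacency matrix pass through a relational message-passing
GNN (one weight matrix per bond-order channel, sum aggregation,
residual connections), producing a per-atom embedding matrix ``X_d``.

* The **formula head** scores every chemical subformula of the molecule.
  Run-length formula encodings act as queries in a scaled dot-product
  attention over the atom embeddings; the attended atom summary is
  concatenated with the encoding, scored by an MLP, softmaxed, gated by
  a positive per-formula weight computed from the attended summary, and
  renormalized to a distribution.

* The **subset head** scores enumerated atom subsets.  Each subset's
  embedding is the mean of its member atoms' rows of ``X_d``,
  concatenated with the run-length encoding of the subset's formula and
  scored by an MLP + softmax.

Training minimises the scaled-L2 spectrum loss
``sum_bins (I_pred^w - I_obs^w)^2`` (default power ``w = 0.5``, damping
dominant peaks) by Adam over minibatches, with the exact observation
model (fragment isotope spectra -> binned, L2-normalized spectrum)
inside the differentiable graph.  Final score layers are zero-initialised,
so an untrained model outputs the uniform distribution over candidates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem import BOND_ORDERS, Molecule, atom_features, build_adjacency, passes_filters
from .formulas import (
    DEFAULT_MAXELEM,
    Formula,
    enumerate_subformulae,
    run_length_encode_batch,
)
from .fragments import (
    AtomSubset,
    FragmentationConfig,
    generate_subsets,
    indicator_matrix,
    subset_formula,
)
from .isotopes import isotope_distribution
from .metrics import stein_dot_product
from .spectrum import (
    DegenerateSpectrumError,
    FragmentProbabilities,
    Spectrum,
    align,
    bin_peaks,
    normalize,
)


class DegenerateInputError(ValueError):
    """An empty candidate batch or an empty atom subset."""


class FilteredMoleculeError(ValueError):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(f"molecule rejected by dataset filters: {reason}")


@dataclass(frozen=True)
class GNNConfig:
    """Backbone and head dimensions.

    Defaults are full-size; the desk-scale experiments in the tests and
    examples use a smaller configuration (4 layers, width 64).
    """

    layers: int = 8
    hidden_dim: int = 256
    nonlinearity: str = "relu"
    residual: bool = True
    seed: int = 0
    attention_dim: int = 32
    mlp_hidden: int = 128
    maxelem: int = DEFAULT_MAXELEM

    def __post_init__(self):
        if self.layers < 1 or self.hidden_dim < 1:
            raise ValueError("layers and hidden_dim must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    intensity_power: float = 0.5
    learning_rate: float = 5e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    resolution: float = 1.0
    prune_below: float = 1e-6

    def __post_init__(self):
        if self.intensity_power <= 0:
            raise ValueError("intensity power must be positive")


_ACT = {"relu": ad.relu, "tanh": ad.tanh, "softplus": ad.softplus}

_N_FEATURES = 17  # rows of chem.atom_features


def _init_params(kind: str, cfg: GNNConfig) -> Dict[str, Tensor]:
    """He/Xavier-initialised weights; score and gate layers start at zero so
    the untrained model emits the uniform candidate distribution."""
    rng = np.random.default_rng(cfg.seed)
    p: Dict[str, Tensor] = {}

    def dense(name, fan_in, fan_out, scale=None):
        s = scale if scale is not None else np.sqrt(2.0 / fan_in)
        p[name] = ad.parameter(rng.normal(0.0, s, size=(fan_in, fan_out)))

    def zeros(name, *shape):
        p[name] = ad.parameter(np.zeros(shape))

    f_in = _N_FEATURES
    for layer in range(cfg.layers):
        dense(f"gnn.{layer}.self", f_in, cfg.hidden_dim)
        for c in range(len(BOND_ORDERS)):
            dense(f"gnn.{layer}.msg{c}", f_in, cfg.hidden_dim)
        zeros(f"gnn.{layer}.bias", 1, cfg.hidden_dim)
        f_in = cfg.hidden_dim

    enc_dim = 8 * cfg.maxelem
    if kind == "formula":
        xavier = lambda fi, fo: np.sqrt(1.0 / fi)
        dense("att.q", enc_dim, cfg.attention_dim, xavier(enc_dim, cfg.attention_dim))
        dense("att.k", cfg.hidden_dim, cfg.attention_dim, xavier(cfg.hidden_dim, cfg.attention_dim))
        dense("att.v", cfg.hidden_dim, cfg.hidden_dim, xavier(cfg.hidden_dim, cfg.hidden_dim))
        _score_mlp_params(dense, zeros, enc_dim + cfg.hidden_dim, cfg.mlp_hidden)
        zeros("gate.w", cfg.hidden_dim, 1)
        zeros("gate.b", 1, 1)
    elif kind == "subset":
        _score_mlp_params(dense, zeros, enc_dim + cfg.hidden_dim, cfg.mlp_hidden)
    else:
        raise ValueError(f"unknown model kind {kind!r}; use 'formula' or 'subset'")
    return p


def gnn_forward(
    x0: np.ndarray, adjacency: np.ndarray, cfg: GNNConfig, params: Dict[str, Tensor]
) -> Tensor:
    """Per-atom embeddings X_d from input features and bond-order adjacency.

    Permutation-equivariant: relabelling atoms permutes the rows.
    """
    if x0.shape[0] != adjacency.shape[0] or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError(
            f"shape mismatch: features {x0.shape} vs adjacency {adjacency.shape}"
        )
    act = _ACT[cfg.nonlinearity]
    channels = [
        (adjacency == order).astype(np.float64) for order in BOND_ORDERS
    ]
    h = Tensor(x0)
    for layer in range(cfg.layers):
        out = h @ params[f"gnn.{layer}.self"]
        for c, mask in enumerate(channels):
            if mask.any():
                out = out + Tensor(mask) @ (h @ params[f"gnn.{layer}.msg{c}"])
        out = act(out + params[f"gnn.{layer}.bias"])
        if cfg.residual and h.shape == out.shape:
            out = out + h
        h = out
    return h


def _score_mlp_params(dense, zeros, d_in: int, width: int) -> None:
    """Two hidden layers; the output layer starts at zero (uniform scores)."""
    dense("mlp.w1", d_in, width)
    zeros("mlp.b1", 1, width)
    dense("mlp.w2", width, width // 2)
    zeros("mlp.b2", 1, width // 2)
    zeros("mlp.w3", width // 2, 1)
    zeros("mlp.b3", 1, 1)


def _score_mlp(feat: Tensor, params: Dict[str, Tensor]) -> Tensor:
    hidden = ad.relu(feat @ params["mlp.w1"] + params["mlp.b1"])
    hidden = ad.relu(hidden @ params["mlp.w2"] + params["mlp.b2"])
    return hidden @ params["mlp.w3"] + params["mlp.b3"]


def formulanet_forward(
    x_d: Tensor, f_enc: np.ndarray, cfg: GNNConfig, params: Dict[str, Tensor]
) -> Tensor:
    """Probability column (n_formulas, 1) over the formula candidates."""
    if f_enc.shape[0] == 0:
        raise DegenerateInputError("empty formula batch")
    fc = Tensor(f_enc)
    q = fc @ params["att.q"]
    k = x_d @ params["att.k"]
    v = x_d @ params["att.v"]
    att_weights = ad.softmax(q @ k.T * (1.0 / np.sqrt(cfg.attention_dim)), axis=-1)
    summary = att_weights @ v  # one attended atom-summary per formula
    scores = _score_mlp(ad.concat([summary, fc], axis=-1), params)
    probs = ad.softmax(scores, axis=0)
    gates = ad.softplus(summary @ params["gate.w"] + params["gate.b"])
    weighted = probs * gates
    return weighted / ad.tsum(weighted, axis=0, keepdims=True)


def subsetnet_forward(
    x_d: Tensor,
    indicator: np.ndarray,
    f_enc: np.ndarray,
    params: Dict[str, Tensor],
) -> Tensor:
    """Probability column (n_subsets, 1) over the subset candidates."""
    if indicator.shape[0] == 0:
        raise DegenerateInputError("empty subset batch")
    sizes = indicator.sum(axis=1)
    if np.any(sizes == 0):
        raise DegenerateInputError("a subset with zero atoms")
    emb = (Tensor(indicator) @ x_d) * Tensor((1.0 / sizes)[:, None])
    scores = _score_mlp(ad.concat([emb, Tensor(f_enc)], axis=-1), params)
    return ad.softmax(scores, axis=0)


# -- candidate preparation -------------------------------------------------

@dataclass
class CandidateBatch:
    """Everything the heads need for one molecule, precomputed.

    ``frag_matrix`` holds each candidate's binned isotopic spectrum as a
    dense row over bins ``0..n_bins-1``, so a predicted spectrum is just
    ``p^T @ frag_matrix`` followed by L2 normalization.
    """

    mol: Molecule
    kind: str
    x0: np.ndarray
    adjacency: np.ndarray
    enc: np.ndarray
    frag_matrix: np.ndarray
    formulas: List[Formula]
    subsets: Optional[List[AtomSubset]] = None
    indicator: Optional[np.ndarray] = None

    @property
    def n_candidates(self) -> int:
        return self.enc.shape[0]

    @property
    def n_bins(self) -> int:
        return self.frag_matrix.shape[1]


def build_candidates(
    mol: Molecule,
    kind: str,
    cfg: GNNConfig,
    resolution: float = 1.0,
    prune_below: float = 1e-6,
    frag_config: FragmentationConfig = FragmentationConfig(),
    min_bins: int = 0,
) -> CandidateBatch:
    """Enumerate candidates and precompute encodings and fragment spectra."""
    if kind == "formula":
        formulas = list(enumerate_subformulae(mol.formula()))
        subsets, indicator = None, None
    elif kind == "subset":
        subs = generate_subsets(mol, frag_config)
        indicator, ordered = indicator_matrix(subs, mol)
        subsets = ordered
        formulas = [subset_formula(s, mol) for s in ordered]
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    enc = run_length_encode_batch(formulas, cfg.maxelem)
    binned = {}
    for f in formulas:
        if f not in binned:
            binned[f] = bin_peaks(isotope_distribution(f, prune_below), resolution)
    n_bins = max(
        [min_bins] + [int(s.bin_index[-1]) + 1 for s in binned.values() if len(s)]
    )
    frag_matrix = np.zeros((len(formulas), n_bins))
    for row, f in enumerate(formulas):
        s = binned[f]
        frag_matrix[row, s.bin_index] = s.intensity
    return CandidateBatch(
        mol, kind, atom_features(mol), build_adjacency(mol), enc, frag_matrix,
        formulas, subsets, indicator,
    )


def _forward_probs(batch: CandidateBatch, cfg: GNNConfig, params: Dict[str, Tensor]) -> Tensor:
    x_d = gnn_forward(batch.x0, batch.adjacency, cfg, params)
    if batch.kind == "formula":
        return formulanet_forward(x_d, batch.enc, cfg, params)
    return subsetnet_forward(x_d, batch.indicator, batch.enc, params)


# -- loss ------------------------------------------------------------------

def scaled_l2_loss(
    predicted: Spectrum, observed: Spectrum, power: float = 0.5
) -> float:
    """sum over bins of (I_pred^power - I_obs^power)^2 on the union grid."""
    _, p, o = align(predicted, observed)  # raises on resolution mismatch
    return float(np.sum((p**power - o**power) ** 2))


def _loss_tensor(
    batch: CandidateBatch, probs: Tensor, obs_dense_pow: np.ndarray, power: float
) -> Tensor:
    dense = probs.T @ Tensor(batch.frag_matrix)  # (1, n_bins)
    pred = ad.l2_normalize(dense)
    diff = ad.power(pred, power) - Tensor(obs_dense_pow)
    return ad.tsum(diff * diff)


# -- trained model ---------------------------------------------------------

@dataclass
class TrainedModel:
    kind: str
    gnn_config: GNNConfig
    training_config: TrainingConfig
    frag_config: FragmentationConfig
    params: Dict[str, Tensor]
    loss_log: List[float] = field(default_factory=list)
    val_log: List[Tuple[int, float]] = field(default_factory=list)

    def save(self, path: str) -> None:
        config = {
            "kind": self.kind,
            "gnn": asdict(self.gnn_config),
            "training": asdict(self.training_config),
            "fragmentation": asdict(self.frag_config),
            "loss_log": self.loss_log,
            "val_log": self.val_log,
        }
        arrays = {k: v.value for k, v in self.params.items()}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(config).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        data = np.load(path if str(path).endswith(".npz") else path + ".npz")
        config = json.loads(bytes(data["__config__"]).decode())
        params = {
            k: ad.parameter(data[k]) for k in data.files if k != "__config__"
        }
        return cls(
            kind=config["kind"],
            gnn_config=GNNConfig(**config["gnn"]),
            training_config=TrainingConfig(**config["training"]),
            frag_config=FragmentationConfig(**config["fragmentation"]),
            params=params,
            loss_log=config["loss_log"],
            val_log=[tuple(t) for t in config["val_log"]],
        )


def _prepare_example(
    mol: Molecule,
    observed: Spectrum,
    kind: str,
    cfg: GNNConfig,
    tcfg: TrainingConfig,
    frag_config: FragmentationConfig,
) -> Tuple[CandidateBatch, np.ndarray]:
    obs = observed if observed.norm == "L2" else normalize(observed, "L2")
    min_bins = int(obs.bin_index[-1]) + 1 if len(obs) else 0
    batch = build_candidates(
        mol, kind, cfg, tcfg.resolution, tcfg.prune_below, frag_config, min_bins
    )
    dense = np.zeros(batch.n_bins)
    dense[obs.bin_index] = obs.intensity
    return batch, dense**tcfg.intensity_power


def train(
    dataset: Sequence[Tuple[Molecule, Spectrum]],
    kind: str,
    gnn_config: GNNConfig = GNNConfig(),
    training_config: TrainingConfig = TrainingConfig(),
    frag_config: FragmentationConfig = FragmentationConfig(),
    validation: Optional[Sequence[Tuple[Molecule, Spectrum]]] = None,
    val_every: int = 5,
    sdp_stop: Optional[float] = None,
    check_filters: bool = False,
    verbose: bool = False,
) -> TrainedModel:
    """Fit a head on (molecule, spectrum) pairs by minibatch Adam.

    Deterministic given the seeds in the configs (single-threaded).  If
    ``validation`` is given, mean Stein dot product against the held-out
    spectra is logged every ``val_every`` epochs; ``sdp_stop`` ends
    training early once that value is reached.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if check_filters:
        for mol, _ in dataset:
            result = passes_filters(mol)
            if not result:
                raise FilteredMoleculeError(result.reason)
    prepared = [
        _prepare_example(m, s, kind, gnn_config, training_config, frag_config)
        for m, s in dataset
    ]
    params = _init_params(kind, gnn_config)
    opt = ad.Adam(list(params.values()), lr=training_config.learning_rate)
    rng = np.random.default_rng(training_config.seed)
    model = TrainedModel(
        kind, gnn_config, training_config, frag_config, params
    )
    n = len(prepared)
    bs = max(1, training_config.batch_size)
    for epoch in range(training_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            opt.zero_grad()
            for i in idx:
                batch, obs_pow = prepared[i]
                probs = _forward_probs(batch, gnn_config, params)
                loss = _loss_tensor(batch, probs, obs_pow, training_config.intensity_power)
                loss.backward()
                epoch_loss += loss.item()
            opt.step()
        model.loss_log.append(epoch_loss / n)
        if validation is not None and (epoch + 1) % val_every == 0:
            sdp = evaluate_sdp(model, validation)
            model.val_log.append((epoch + 1, sdp))
            if verbose:
                print(f"epoch {epoch + 1}: loss {model.loss_log[-1]:.5f} val SDP {sdp:.4f}")
            if sdp_stop is not None and sdp >= sdp_stop:
                break
        elif verbose:
            print(f"epoch {epoch + 1}: loss {model.loss_log[-1]:.5f}")
    return model


def predict_fragment_probabilities(
    mol: Molecule, model: TrainedModel
) -> FragmentProbabilities:
    """Run the trained head on one molecule; returns the candidate distribution."""
    batch = build_candidates(
        mol,
        model.kind,
        model.gnn_config,
        model.training_config.resolution,
        model.training_config.prune_below,
        model.frag_config,
    )
    probs = _forward_probs(batch, model.gnn_config, model.params).value.ravel()
    keys: Sequence[Union[Formula, AtomSubset]] = (
        batch.formulas if model.kind == "formula" else batch.subsets
    )
    total = probs.sum()
    return FragmentProbabilities([(k, float(p) / total) for k, p in zip(keys, probs)])


def predict_spectrum(
    mol: Molecule,
    model: TrainedModel,
    resolution: Optional[float] = None,
    check_filters: bool = False,
) -> Spectrum:
    """End-to-end prediction: enumerate, score, assemble, L2-normalize.

    The fragment distribution does not depend on the resolution, so the
    same molecule can be rendered at any bin width.
    """
    if check_filters:
        result = passes_filters(mol)
        if not result:
            raise FilteredMoleculeError(result.reason)
    res = model.training_config.resolution if resolution is None else resolution
    batch = build_candidates(
        mol, model.kind, model.gnn_config, res,
        model.training_config.prune_below, model.frag_config,
    )
    probs = _forward_probs(batch, model.gnn_config, model.params).value.ravel()
    dense = probs @ batch.frag_matrix
    nz = np.nonzero(dense)[0]
    if len(nz) == 0:
        raise DegenerateSpectrumError("prediction produced no peaks")
    return normalize(Spectrum(nz.astype(np.int64), dense[nz], res), "L2")


def evaluate_sdp(
    model: TrainedModel, dataset: Sequence[Tuple[Molecule, Spectrum]]
) -> float:
    """Mean Stein dot product of predictions against reference spectra."""
    scores = [
        stein_dot_product(predict_spectrum(mol, model, spec.resolution), spec)
        for mol, spec in dataset
    ]
    return float(np.mean(scores))
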