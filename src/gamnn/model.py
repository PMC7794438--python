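"""The GAM-NN architecture and exact additive contribution extraction.

Each continuous feature x_j feeds its own small fully connected subnetwork
(1 -> layer_size -> ... -> layer_size) whose last layer is a single tanh
unit, so the subnetwork output g_j(x_j) is always inside (-1, 1).  Binary
features bypass the subnetworks entirely: they connect directly to the
final logistic layer.  The bottleneck outputs and the raw binary inputs are
concatenated and combined linearly,

    logit(x) = b0 + sum_cont w_j * g_j(x_j) + sum_bin w_b * x_b,

and the predicted risk is sigmoid(logit).  The model is interpretable by
construction: the additive term w_j * g_j(x_j) (or w_b * x_b) IS feature
j's contribution to the log-odds, no post-hoc attribution needed.

The network is implemented directly on NumPy arrays.  All per-feature
subnetworks share one architecture, so their parameters are stored stacked
along a leading feature axis and evaluated in a single batched einsum;
forward/backward cost is O(n_samples * n_continuous * layer_size) per layer.

Dropout (inverted, training only) acts on subnetwork hidden activations;
neither raw inputs nor the concatenated bottleneck outputs are dropped, which
keeps the additive decomposition stable.  The L2 penalty covers every weight
matrix, including the logistic weights, but no bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import Dataset, FeatureSchema, SchemaError

__all__ = [
    "GamnnConfig",
    "GamnnModel",
    "ContributionTable",
    "build_model",
    "forward_logit",
    "predict_proba",
    "feature_contribution",
    "contributions_table",
    "sigmoid",
]

# hyperparameter grid assessed during model development
GRID_HIDDEN_LAYERS = (1, 2, 3, 4)
GRID_LAYER_SIZES = (10, 40, 50, 90, 100)
GRID_ACTIVATIONS = ("relu", "tanh")
GRID_DROPOUT = (0.25, 0.5, 0.9)
GRID_L2 = (0.001, 0.0001)


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


@dataclass
class GamnnConfig:
    """Architecture + training hyperparameters.

    Defaults are the selected final configuration: one hidden layer of 50
    tanh units per subnetwork, dropout 0.5, L2 1e-4, positive class weighted
    100x, batch size 256, Adam at its conventional 1e-3 with
    reduce-on-plateau (factor 10, patience 5 epochs), at most 100 epochs.
    """

    n_hidden_layers: int = 1
    layer_size: int = 50
    hidden_activation: str = "tanh"
    dropout_p: float = 0.5
    l2_lambda: float = 0.0001
    positive_class_weight: float = 100.0
    batch_size: int = 256
    max_epochs: int = 100
    learning_rate: float = 0.001
    lr_reduce_factor: float = 10.0
    lr_patience_epochs: int = 5
    lr_min_delta: float = 1e-4
    min_learning_rate: float = 1e-6
    early_stop: bool = False
    intercept_warm_start: bool = True
    center_penalty: float = 1.0
    standardize_binary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_activation not in GRID_ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        if not 1 <= self.n_hidden_layers:
            raise ValueError("n_hidden_layers must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.positive_class_weight <= 0:
            raise ValueError("positive_class_weight must be positive")

    def in_grid(self) -> bool:
        """Whether every grid-constrained field sits on the search grid."""
        return (
            self.n_hidden_layers in GRID_HIDDEN_LAYERS
            and self.layer_size in GRID_LAYER_SIZES
            and self.hidden_activation in GRID_ACTIVATIONS
            and self.dropout_p in GRID_DROPOUT
            and self.l2_lambda in GRID_L2
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "GamnnConfig":
        return cls(**d)


class ContributionTable:
    """Per-sample, per-feature additive contributions on the logit scale.

    ``intercept + contributions.sum(axis=1)`` reconstructs the forward logit
    for every row (additivity is exact up to float accumulation).
    """

    def __init__(
        self,
        contributions: np.ndarray,
        intercept: float,
        logits: np.ndarray,
        feature_names: list[str],
        feature_kinds: list[str],
    ):
        self.contributions = np.asarray(contributions, dtype=float)
        self.intercept = float(intercept)
        self.logits = np.asarray(logits, dtype=float)
        self.feature_names = list(feature_names)
        self.feature_kinds = list(feature_kinds)
        resid = np.abs(self.intercept + self.contributions.sum(axis=1) - self.logits)
        if resid.size and resid.max() > 1e-6:
            raise AssertionError(
                f"additivity violated: max residual {resid.max():.3g}"
            )

    @property
    def n_samples(self) -> int:
        return self.contributions.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None
        return self.contributions[:, j]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class GamnnModel:
    """Parameters and forward/backward passes of the additive network.

    Parameter layout (all float64):

    - ``hW{l}``: (n_cont, d_in, d_out), ``hb{l}``: (n_cont, d_out) —
      hidden layer ``l`` of every continuous-feature subnetwork, stacked.
    - ``V``: (n_cont, layer_size), ``c``: (n_cont,) — the single-unit tanh
      bottleneck closing each subnetwork.
    - ``w``: (n_features,) logistic weights in schema order (continuous and
      binary alike), ``b0``: () intercept.
    """

    def __init__(self, schema: FeatureSchema, config: GamnnConfig):
        self.schema = schema
        self.config = config
        self.feature_names = schema.feature_names
        self.feature_kinds = [s.kind for s in schema.specs]
        self.cont_idx = np.array(
            [j for j, s in enumerate(schema.specs) if s.kind == "continuous"], dtype=int
        )
        self.bin_idx = np.array(
            [j for j, s in enumerate(schema.specs) if s.kind == "binary"], dtype=int
        )
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # ------------------------------------------------------------------ setup
    # first hidden layer: weights and biases uniform on +-KINK_SPREAD so the
    # units' kinks / saturation points tile the standardized data range —
    # with a zero-bias Glorot start every unit of a 1-input layer is
    # near-linear over the data and the subnetwork begins (and tends to stay)
    # monotone
    KINK_SPREAD = 2.5

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        Fc = len(self.cont_idx)
        H = self.config.layer_size
        L = self.config.n_hidden_layers
        p: dict[str, np.ndarray] = {}
        if Fc:
            d_in = 1
            for l in range(L):
                if l == 0:
                    p["hW0"] = rng.uniform(-self.KINK_SPREAD, self.KINK_SPREAD, (Fc, 1, H))
                    p["hb0"] = rng.uniform(-self.KINK_SPREAD, self.KINK_SPREAD, (Fc, H))
                else:
                    p[f"hW{l}"] = _glorot(rng, (Fc, d_in, H), d_in, H)
                    p[f"hb{l}"] = np.zeros((Fc, H))
                d_in = H
            # V starts at zero: every shape function begins exactly flat
            # (g_j == 0) and acquires amplitude only where the data demand
            # it, so null features stay near zero contribution; not a saddle
            # because the logistic weights start at 1
            p["V"] = np.zeros((Fc, H))
            p["c"] = np.zeros(Fc)
        # unit pass-through for continuous bottleneck outputs: the logistic
        # layer provides amplitude from the first step, so subnetworks need
        # not saturate their tanh bottleneck to move the logit; binary
        # weights start at zero like a logistic regression
        w = np.zeros(len(self.feature_names))
        w[self.cont_idx] = 1.0
        p["w"] = w
        p["b0"] = np.zeros(())
        self.params = p

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.config.hidden_activation == "relu":
            return np.maximum(z, 0.0)
        return np.tanh(z)

    # ---------------------------------------------------------------- forward
    def _check_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input has {X.shape[1]} columns, model expects {self.n_features}"
            )
        if np.isnan(X).any():
            raise ValueError("input contains missing values; preprocess first")
        return X

    def bottleneck_outputs(self, X: np.ndarray) -> np.ndarray:
        """g_j(x_j) in (-1, 1) for every continuous feature; (n, n_cont)."""
        X = self._check_matrix(X)
        out, _ = self._forward(X, training=False, rng=None)
        return out["G"]

    def _forward(
        self, X: np.ndarray, training: bool, rng: np.random.Generator | None
    ) -> tuple[dict, dict]:
        p = self.params
        cfg = self.config
        cache: dict = {"X": X}
        n = X.shape[0]
        if len(self.cont_idx):
            A = X[:, self.cont_idx][:, :, None]  # (n, Fc, 1)
            As, Zs, masks = [A], [], []
            for l in range(cfg.n_hidden_layers):
                Z = np.einsum("nfi,fio->nfo", A, p[f"hW{l}"]) + p[f"hb{l}"][None]
                Hpre = self._act(Z)
                if training and cfg.dropout_p > 0.0:
                    assert rng is not None
                    mask = (rng.random(Hpre.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
                    A = Hpre * mask
                else:
                    mask = None
                    A = Hpre
                Zs.append(Z)
                masks.append(mask)
                As.append(A)
            Zb = np.einsum("nfi,fi->nf", A, p["V"]) + p["c"][None]
            G = np.tanh(Zb)
            cache.update(As=As, Zs=Zs, masks=masks, G=G)
            logit = G @ p["w"][self.cont_idx]
        else:
            G = np.zeros((n, 0))
            cache.update(G=G)
            logit = np.zeros(n)
        if len(self.bin_idx):
            logit = logit + X[:, self.bin_idx] @ p["w"][self.bin_idx]
        logit = logit + p["b0"]
        out = {"logit": logit, "G": G}
        return out, cache

    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode logits for a matrix of preprocessed rows."""
        X = self._check_matrix(X)
        out, _ = self._forward(X, training=False, rng=None)
        return out["logit"]

    # --------------------------------------------------------------- backward
    def forward_backward(
        self,
        X: np.ndarray,
        dlogit_fn,
        training: bool = True,
        rng: np.random.Generator | None = None,
        dG_extra=None,
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """One pass: compute logits, obtain dL/dlogit from ``dlogit_fn`` and
        return (logits, gradient dict keyed like ``params``).

        L2 is *not* added here; the optimizer adds ``2 * l2 * W`` for weight
        matrices so loss bookkeeping stays explicit in the training loop.
        ``dG_extra(G)`` may supply an additional gradient on the bottleneck
        outputs (used for the sum-to-zero identifiability penalty).
        """
        X = self._check_matrix(X)
        p = self.params
        cfg = self.config
        out, cache = self._forward(X, training=training, rng=rng)
        logit = out["logit"]
        dlogit = dlogit_fn(logit)  # (n,)

        g: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in p.items()}
        g["b0"] = np.asarray(dlogit.sum())
        if len(self.bin_idx):
            g["w"][self.bin_idx] = X[:, self.bin_idx].T @ dlogit
        if len(self.cont_idx):
            G = cache["G"]
            g["w"][self.cont_idx] = G.T @ dlogit
            dG = dlogit[:, None] * p["w"][self.cont_idx][None, :]  # (n, Fc)
            if dG_extra is not None:
                dG = dG + dG_extra(G)
            dZb = dG * (1.0 - G * G)
            A_last = cache["As"][-1]
            g["V"] = np.einsum("nfi,nf->fi", A_last, dZb)
            g["c"] = dZb.sum(axis=0)
            dA = dZb[:, :, None] * p["V"][None, :, :]  # (n, Fc, H)
            for l in range(cfg.n_hidden_layers - 1, -1, -1):
                mask = cache["masks"][l]
                if mask is not None:
                    dA = dA * mask
                Z = cache["Zs"][l]
                if cfg.hidden_activation == "relu":
                    dZ = dA * (Z > 0.0)
                else:
                    t = np.tanh(Z)
                    dZ = dA * (1.0 - t * t)
                A_prev = cache["As"][l]
                g[f"hW{l}"] = np.einsum("nfi,nfo->fio", A_prev, dZ)
                g[f"hb{l}"] = dZ.sum(axis=0)
                dA = np.einsum("nfo,fio->nfi", dZ, p[f"hW{l}"])
        return logit, g

    # ----------------------------------------------------------- predictions
    def predict_logit(self, x: np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float(self.forward_logits(x[None, :])[0])
        return self.forward_logits(x)

    def predict_proba(self, x: np.ndarray) -> float | np.ndarray:
        return sigmoid(self.predict_logit(x))

    def feature_contribution(self, x: np.ndarray, name: str) -> float:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("feature_contribution takes a single feature vector")
        if name not in self.feature_names:
            raise SchemaError(f"unknown feature {name!r}")
        j = self.feature_names.index(name)
        w_j = float(self.params["w"][j])
        if self.feature_kinds[j] == "binary":
            return w_j * float(x[j])
        G = self.bottleneck_outputs(x[None, :])[0]
        pos = int(np.where(self.cont_idx == j)[0][0])
        return w_j * float(G[pos])

    def contributions(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(contribution matrix in schema order, logits)."""
        X = self._check_matrix(X)
        out, _ = self._forward(X, training=False, rng=None)
        C = np.zeros_like(X)
        if len(self.cont_idx):
            C[:, self.cont_idx] = out["G"] * self.params["w"][self.cont_idx][None, :]
        if len(self.bin_idx):
            C[:, self.bin_idx] = X[:, self.bin_idx] * self.params["w"][self.bin_idx][None, :]
        return C, out["logit"]

    # ---------------------------------------------------------- serialization
    def save(self, path: str | Path) -> None:
        """Portable JSON archive: config + schema + full-precision weights."""
        doc = {
            "format": "gamnn-model",
            "version": 1,
            "config": self.config.to_dict(),
            "schema": self.schema.to_dict(),
            "params": {k: np.asarray(v).tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "GamnnModel":
        from .schema import FeatureSchema as FS, FeatureSpec

        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "gamnn-model":
            raise ValueError(f"{path} is not a gamnn model archive")
        sch = doc["schema"]
        specs = tuple(
            FeatureSpec(
                name=e["name"],
                kind=e["kind"],
                impute_policy=e.get("impute_policy", ""),
                constant_value=e.get("constant_value"),
                clip_min=e.get("clip_min"),
                clip_max=e.get("clip_max"),
            )
            for e in sch["features"]
        )
        schema = FS(specs=specs, outcome_name=sch["outcome"])
        model = cls(schema, GamnnConfig.from_dict(doc["config"]))
        for k, v in doc["params"].items():
            model.params[k] = np.asarray(v, dtype=float).reshape(model.params[k].shape)
        return model


# ------------------------------------------------------- module-level surface
def build_model(schema: FeatureSchema, config: GamnnConfig | None = None) -> GamnnModel:
    """Construct an untrained GAM-NN for a schema.

    One subnetwork per continuous feature; binary features connect directly
    to the logistic layer.  Initialization is Glorot-uniform, deterministic
    in ``config.seed``.
    """
    if config is None:
        config = GamnnConfig()
    return GamnnModel(schema, config)


def forward_logit(model: GamnnModel, x: np.ndarray) -> float:
    return float(model.predict_logit(np.asarray(x, dtype=float)))


def predict_proba(model: GamnnModel, x: np.ndarray) -> float:
    return float(sigmoid(forward_logit(model, x)))


def feature_contribution(model: GamnnModel, x: np.ndarray, name: str) -> float:
    return model.feature_contribution(np.asarray(x, dtype=float), name)


def contributions_table(model: GamnnModel, ds: Dataset) -> ContributionTable:
    """Exact additive decomposition of every sample's logit."""
    C, logits = model.contributions(ds.values)
    return ContributionTable(
        C,
        intercept=float(model.params["b0"]),
        logits=logits,
        feature_names=model.feature_names,
        feature_kinds=model.feature_kinds,
    )
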