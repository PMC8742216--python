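"""Interpretable time-invariant / time-variant (TITV) risk model and baselines.

The model factors the risk of AKI into three cooperating parts:

* **Time-invariant module** — a gate network shared across features
  reads each feature's whole-window summary (masked time-average ``u_f``,
  observation fraction ``m_f``, and their population z-scores) and emits
  a bounded per-feature scale ``gamma_f`` in (0, 2) (feature-wise linear
  modulation, FiLM).  Inputs are deviation-coded against the training
  population: an observed cell carries ``value - population mean``, a
  missing cell carries exactly 0 ("population-normal").  The modulated
  input is ``X~_tf = gamma_f * (X_tf - mu_f) * M_tf + delta_f * M_tf``;
  the learnable shift ``delta_f`` is carried per observation, so
  ordering intensity is usable evidence credited to the analyte that
  was ordered.
* **Time-variant module** — a bidirectional GRU over the modulated
  daily windows with self-attention over time: window weights ``a_t``
  (softmax over windows) locate the evidence in time.  Attention
  deliberately does not redistribute weight across features — a dynamic
  per-feature attention would let the recurrent module reroute risk
  through arbitrary channels and make the reported feature importance
  decorative.  ``alpha_tf = a_t / F`` is the reported time-variant
  importance (sums to 1 over all cells).
* **Prediction module** — an additive head,
  ``logit = sum_tf w_f * a_t * X~_tf + bias``, so each cell's term is
  an exact signed attribution of the final logit.  The reported
  time-invariant importance ``beta_f`` is the feature's share of the
  total absolute logit contribution, marginalized over time; it credits
  whichever static channel (value gain ``w_f * gamma_f`` or observation
  term ``w_f * delta_f``) the evidence actually flows through.

Training minimizes class-weighted binary cross-entropy with Adam
(gradient clipping, per-epoch learning-rate decay, a ramped entropy
penalty on beta and an L1 penalty on the static head weights) and
early-stops on validation AUROC.  GRU and bidirectional-GRU baselines
(last hidden state -> linear) share the loop; the logistic baseline on
the flattened window vector uses scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._autodiff import (Adam, Tensor, concat, sigmoid_np, softmax, stack,
                        weighted_bce_with_logits)


@dataclass
class TitvConfig:
    hidden_size: int = 64
    film_hidden: int = 64
    dropout: float = 0.0
    learning_rate: float = 0.02
    lr_decay: float = 0.97  # per-epoch multiplicative decay
    max_epochs: int = 80
    early_stop_patience: int = 15
    batch_size: int = 128
    positive_class_weight: float | str = "auto"  # n_neg / n_pos when "auto"
    grad_clip: float = 5.0  # global gradient-norm ceiling per step
    beta_entropy: float = 0.05  # entropy penalty on beta -> sparse, legible beta
    w_l1: float = 0.02  # L1 on static head weights -> prune nuisance features
    seed: int = 0
    use_mask: bool = False

    def __post_init__(self) -> None:
        if self.hidden_size <= 0 or self.film_hidden <= 0:
            raise ValueError("hidden sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TitvOutput:
    """Per-sample risk plus exact additive attributions."""

    risk: float
    beta: np.ndarray            # (F,), >= 0, sums to 1
    alpha: np.ndarray           # (T, F), >= 0, sums to 1
    contributions: np.ndarray   # (T, F) signed logit-space attributions
    logit_bias: float

    @property
    def logit(self) -> float:
        return float(self.contributions.sum() + self.logit_bias)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def init_titv_params(T: int, F: int, config: TitvConfig,
                     rng: np.random.Generator) -> dict[str, Tensor]:
    H, FH = config.hidden_size, config.film_hidden
    Fin = 2 * F if config.use_mask else F
    p: dict[str, np.ndarray] = {
        # feature-wise gate network, shared across features: each gamma_f
        # is 2*sigmoid(g([u_f, m_f, z_u, z_m]) + base_f) of that feature's
        # own pooled summary.  Computing the gate per feature (rather than
        # from the joint summary) keeps the gate identifiable as that
        # feature's responsiveness: a single channel cannot act as a
        # global risk dial.  The shift delta is a per-feature bias carried
        # on each observation.
        "Wg": _glorot(rng, 4, FH), "bg": np.zeros(FH),
        "vg": _glorot(rng, FH, 1),
        # 2*sigmoid(base)=1 at start: modulation begins at identity
        "g_base": np.zeros(F),
        # direct skip from the abnormality z-score into the gate: the
        # gate starts out evidence-responsive (gamma rises with how far
        # the patient's pooled mean sits above the population mean)
        # instead of having to discover that monotonicity from scratch
        "g_skip": np.ones(()),
        "delta": np.zeros(F),
        # population statistics of the pooled summaries (set from the
        # training split at fit time; not gradient-trained) so the gate
        # sees "how abnormal is this feature for this patient" on a
        # comparable scale for every analyte
        "u_mean": np.zeros(F), "u_sd": np.ones(F),
        "m_mean": np.zeros(F), "m_sd": np.ones(F),
        "x_mean": np.zeros(F),
        "Wa": _glorot(rng, 2 * H, H), "ba": np.zeros(H),
        "va": _glorot(rng, H, 1),
        "w": rng.normal(0.0, 1.0, size=F), "bias": np.zeros(()),
    }
    for d in ("f", "b"):
        p[f"Wx_{d}"] = _glorot(rng, Fin, 3 * H)
        p[f"Wh_{d}"] = _glorot(rng, H, 3 * H)
        p[f"bg_{d}"] = np.zeros(3 * H)
    return {k: Tensor(v, requires_grad=k not in STATS_KEYS) for k, v in p.items()}


STATS_KEYS = ("u_mean", "u_sd", "m_mean", "m_sd", "x_mean")


def _set_summary_stats(params: dict[str, Tensor], X: np.ndarray,
                       M: np.ndarray) -> None:
    """Freeze training-population statistics of the pooled summaries."""
    u = (M * X).sum(axis=1) / np.maximum(1.0, M.sum(axis=1))
    m = M.mean(axis=1)
    # sd floors keep the derived z-scores bounded for near-constant
    # summaries (inputs are min-max normalized, so 0.05 is 5% of range)
    params["u_mean"].data = u.mean(axis=0)
    params["u_sd"].data = np.maximum(u.std(axis=0), 0.05)
    params["m_mean"].data = m.mean(axis=0)
    params["m_sd"].data = np.maximum(m.std(axis=0), 0.05)
    # observed mean per feature: inputs are deviation-coded against it,
    # which makes an imputed (missing) cell exactly population-normal
    obs = M.sum(axis=(0, 1))
    params["x_mean"].data = np.where(
        obs > 0, (M * X).sum(axis=(0, 1)) / np.maximum(obs, 1.0), 0.0)


def _gru_direction(params: dict[str, Tensor], xs: list[Tensor], d: str,
                   H: int) -> list[Tensor]:
    """Run one GRU direction over a list of (B, Fin) inputs."""
    Wx, Wh, bg = params[f"Wx_{d}"], params[f"Wh_{d}"], params[f"bg_{d}"]
    B = xs[0].shape[0]
    h = Tensor(np.zeros((B, H)))
    out = []
    for x in xs:
        gx = x @ Wx + bg
        gh = h @ Wh
        z = (gx[:, :H] + gh[:, :H]).sigmoid()
        r = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        h = (1.0 - z) * n + z * h
        out.append(h)
    return out


def _titv_graph(params: dict[str, Tensor], X: np.ndarray, M: np.ndarray,
                config: TitvConfig,
                drop_rng: np.random.Generator | None = None) -> dict:
    """Batched forward pass; returns graph tensors for loss and outputs."""
    if X.ndim != 3 or X.shape != M.shape:
        raise ValueError("X and M must both be (B, T, F)")
    B, T, F = X.shape
    if params["g_base"].shape[0] != F:
        raise ValueError(f"model fitted for F={params['g_base'].shape[0]}, got {F}")
    for name, t in params.items():
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite values in parameter {name}")
    H = config.hidden_size

    # time-invariant module: per-feature pooled summary -> FiLM gate
    denom = np.maximum(1.0, M.sum(axis=1))
    u = (M * X).sum(axis=1) / denom                   # (B, F) pooled mean
    m_frac = M.mean(axis=1)                           # (B, F) obs. fraction
    zu = np.clip((u - params["u_mean"].data) / params["u_sd"].data, -4.0, 4.0)
    zm = np.clip((m_frac - params["m_mean"].data) / params["m_sd"].data,
                 -4.0, 4.0)
    summary = Tensor(np.stack([u, m_frac, zu, zm], axis=-1))  # (B, F, 4)
    hg = (summary @ params["Wg"] + params["bg"]).tanh()   # (B, F, FH)
    # bounded gate in (0, 2): keeps the modulated inputs on the scale the
    # recurrent module was initialized for (unbounded scales destabilize it)
    gamma = ((hg @ params["vg"])[:, :, 0] + params["g_skip"] * Tensor(zu)
             + params["g_base"]).sigmoid() * 2.0
    delta = params["delta"]

    # deviation coding: observed cells carry (value - population mean),
    # missing cells carry exactly 0, i.e. "population-normal"; without
    # this, every positively weighted observation inflates the logit and
    # the head is forced to learn a block of negative compensator
    # weights on common analytes that pollutes beta
    # the shift is carried per observation (delta * mask): each recorded
    # measurement of analyte f contributes a learnable "this test was
    # ordered" term, so ordering intensity is usable evidence and is
    # credited to the analyte that was ordered; missing cells carry
    # exactly 0 and contribute nothing
    Xc = (X - params["x_mean"].data) * M
    xs = []
    for t in range(T):
        xt = gamma * Tensor(Xc[:, t, :]) + delta * Tensor(M[:, t, :])
        xs.append(concat([xt, Tensor(M[:, t, :])], axis=1)
                  if config.use_mask else xt)
    xmod = [x[:, :F] if config.use_mask else x for x in xs]

    # time-variant module: BGRU + factorized self-attention
    hf = _gru_direction(params, xs, "f", H)
    hb = _gru_direction(params, xs[::-1], "b", H)[::-1]
    hs = [concat([f, b], axis=1) for f, b in zip(hf, hb)]  # T x (B, 2H)
    if drop_rng is not None and config.dropout > 0:
        keep = 1.0 - config.dropout
        hs = [h * Tensor(drop_rng.random(h.shape) < keep) * (1.0 / keep)
              for h in hs]
    scores = concat([(h @ params["Wa"] + params["ba"]).tanh() @ params["va"]
                     for h in hs], axis=1)            # (B, T)
    a = softmax(scores, axis=1)

    # prediction module: additive head; each cell's term is an exact
    # signed attribution of the final logit.  Attention redistributes
    # weight over time only; per-feature weight comes solely from the
    # static gain w_f * gamma_f, so the reported beta is the true path
    # the evidence takes (a dynamic per-feature attention would let the
    # recurrent module reroute risk through arbitrary features and turn
    # beta into decoration).
    ones_f = Tensor(np.ones((1, F)))
    contribs = []
    alphas = []
    for t in range(T):
        alpha_t = a[:, t:t + 1] * (ones_f * (1.0 / F))  # (B, F), sums to 1/T
        alphas.append(alpha_t)
        contribs.append(params["w"] * a[:, t:t + 1] * xmod[t])
    cstack = stack(contribs, axis=1)                  # (B, T, F)
    logit = cstack.sum(axis=(1, 2)) + params["bias"]
    # time-invariant importance: each feature's share of the total
    # absolute logit contribution, marginalized over time.  This credits
    # whichever static channel (value gain w*gamma or observation term
    # w*delta) the evidence actually flows through; uniform when the
    # sample generates no contributions at all.
    absmass = cstack.abs().sum(axis=1) + 1e-12        # (B, F)
    beta = absmass / absmass.sum(axis=1, keepdims=True)
    return {"logit": logit, "beta": beta,
            "alpha": stack(alphas, axis=1),           # (B, T, F)
            "contributions": cstack,
            # normalized entropy of beta: pushes the importance profile
            # toward concentration without shrinking the gate's absolute
            # level (beta is scale-invariant in gamma, so penalizing the
            # gate magnitude would only saturate it, not sparsify beta)
            "penalty": -(beta * (beta + 1e-12).log()).sum(axis=1).mean()
            * (1.0 / np.log(F)),
            "w_l1": params["w"].abs().mean()}


class TitvModel:
    """Fitted TITV network: parameters, config, and window geometry."""

    def __init__(self, params: dict[str, Tensor], config: TitvConfig,
                 T: int, F: int, analytes: list[str] | None = None):
        self.params = params
        self.config = config
        self.T, self.F = T, F
        self.analytes = analytes
        self.history: list[dict] = []

    def predict_proba(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        g = _titv_graph(self.params, X, M, self.config)
        return sigmoid_np(g["logit"].data)

    def forward(self, X: np.ndarray, M: np.ndarray) -> TitvOutput:
        """Single-sample forward: X, M of shape (T, F)."""
        g = _titv_graph(self.params, X[None], M[None], self.config)
        return TitvOutput(
            risk=float(sigmoid_np(g["logit"].data)[0]),
            beta=g["beta"].data[0],
            alpha=g["alpha"].data[0],
            contributions=g["contributions"].data[0],
            logit_bias=float(self.params["bias"].data),
        )

    def explain(self, X: np.ndarray, M: np.ndarray, top_k: int = 10,
                by: str = "importance") -> list[tuple[str | int, int, float]]:
        """Rank (feature, window) cells by alpha*beta or |contribution|.

        Returns (analyte, window_index, score) triples, highest first;
        scores are normalized to total mass 1 (relative importance);
        ``top_k`` is capped at T*F.
        """
        out = self.forward(X, M)
        score = (out.alpha * out.beta[None, :] if by == "importance"
                 else np.abs(out.contributions))
        score = score / max(score.sum(), 1e-12)
        top_k = min(top_k, score.size)
        flat = np.argsort(score, axis=None)[::-1][:top_k]
        result = []
        for idx in flat:
            t, f = np.unravel_index(idx, score.shape)
            name = self.analytes[f] if self.analytes else int(f)
            result.append((name, int(t), float(score[t, f])))
        return result

    def importance_heatmap(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        """(T, F) relative importance matrix (mass 1) for case heatmaps."""
        out = self.forward(X, M)
        score = out.alpha * out.beta[None, :]
        return score / max(score.sum(), 1e-12)

    def save(self, path: str) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        meta = {"config": asdict(self.config), "T": self.T, "F": self.F,
                "analytes": self.analytes, "kind": "titv", "version": 1}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TitvModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: Tensor(z[k], requires_grad=True)
                      for k in z.files if k != "__meta__"}
        cfg = TitvConfig(**meta["config"])
        model = cls(params, cfg, meta["T"], meta["F"], meta.get("analytes"))
        return model


def titv_forward(params: dict[str, Tensor], X: np.ndarray, M: np.ndarray,
                 config: TitvConfig | None = None) -> TitvOutput:
    """Functional single-sample forward pass (X, M of shape (T, F))."""
    config = config or TitvConfig()
    g = _titv_graph(params, X[None], M[None], config)
    return TitvOutput(
        risk=float(sigmoid_np(g["logit"].data)[0]),
        beta=g["beta"].data[0],
        alpha=g["alpha"].data[0],
        contributions=g["contributions"].data[0],
        logit_bias=float(params["bias"].data),
    )


def _class_weights(y: np.ndarray, config: TitvConfig) -> np.ndarray:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training labels must contain both classes")
    w_pos = (n_neg / n_pos if config.positive_class_weight == "auto"
             else float(config.positive_class_weight))
    return np.where(y > 0, w_pos, 1.0)


def _train_loop(graph_fn, params: dict[str, Tensor],
                train: tuple[np.ndarray, np.ndarray, np.ndarray],
                valid: tuple[np.ndarray, np.ndarray, np.ndarray],
                config: TitvConfig) -> list[dict]:
    Xtr, Mtr, ytr = train
    Xva, Mva, yva = valid
    weights = _class_weights(ytr, config)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    opt = Adam(list(params.values()), lr=config.learning_rate)
    best_auc, best_state, patience_left = -np.inf, None, config.early_stop_patience
    history = []
    n = len(ytr)
    for epoch in range(config.max_epochs):
        opt.lr = config.learning_rate * config.lr_decay ** epoch
        # ramp the gate penalty in over training: prune after the fit,
        # not before it (full-strength shrinkage at epoch 0 can collapse
        # the gate into saturation before any signal is learned)
        lam = config.beta_entropy * epoch / max(1, config.max_epochs - 1)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            g = graph_fn(params, Xtr[idx], Mtr[idx],
                         drop_rng if config.dropout > 0 else None)
            loss = weighted_bce_with_logits(g["logit"], ytr[idx], weights[idx])
            if "penalty" in g and lam > 0:
                loss = loss + lam * g["penalty"]
            if "w_l1" in g and config.w_l1 > 0:
                loss = loss + config.w_l1 * g["w_l1"]
            opt.zero_grad()
            loss.backward()
            # clip the global gradient norm: one bad minibatch (heavily
            # weighted positives) can otherwise throw the recurrent
            # weights into saturation they never recover from
            if config.grad_clip > 0:
                total = np.sqrt(sum(float((t.grad ** 2).sum())
                                    for t in params.values()
                                    if t.grad is not None))
                if total > config.grad_clip:
                    scale = config.grad_clip / total
                    for t in params.values():
                        if t.grad is not None:
                            t.grad = t.grad * scale
            opt.step()
            losses.append(float(loss.data))
        val_scores = sigmoid_np(graph_fn(params, Xva, Mva, None)["logit"].data)
        val_auc = (roc_auc_score(yva, val_scores)
                   if len(np.unique(yva)) > 1 else np.nan)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "valid_auroc": float(val_auc)})
        if np.isnan(val_auc) or val_auc > best_auc + 1e-6:
            if not np.isnan(val_auc):
                best_auc = val_auc
            best_state = {k: t.data.copy() for k, t in params.items()}
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        for k, t in params.items():
            t.data = best_state[k]
    return history


def fit_titv(train: tuple[np.ndarray, np.ndarray, np.ndarray],
             valid: tuple[np.ndarray, np.ndarray, np.ndarray],
             config: TitvConfig | None = None,
             analytes: list[str] | None = None) -> TitvModel:
    """Train a TITV model; returns the best-validation-AUROC checkpoint."""
    config = config or TitvConfig()
    Xtr = train[0]
    _, T, F = Xtr.shape
    rng = np.random.default_rng(config.seed)
    params = init_titv_params(T, F, config, rng)
    _set_summary_stats(params, train[0], train[1])

    def graph_fn(p, X, M, drop_rng):
        return _titv_graph(p, X, M, config, drop_rng)

    history = _train_loop(graph_fn, params, train, valid, config)
    model = TitvModel(params, config, T, F, analytes)
    model.history = history
    return model


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def init_gru_params(T: int, F: int, config: TitvConfig, bidirectional: bool,
                    rng: np.random.Generator) -> dict[str, Tensor]:
    H = config.hidden_size
    p: dict[str, np.ndarray] = {}
    dirs = ("f", "b") if bidirectional else ("f",)
    for d in dirs:
        p[f"Wx_{d}"] = _glorot(rng, F, 3 * H)
        p[f"Wh_{d}"] = _glorot(rng, H, 3 * H)
        p[f"bg_{d}"] = np.zeros(3 * H)
    p["Wo"] = _glorot(rng, H * len(dirs), 1)
    p["bo"] = np.zeros(())
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def _gru_graph(params: dict[str, Tensor], X: np.ndarray, M: np.ndarray,
               config: TitvConfig, bidirectional: bool,
               drop_rng: np.random.Generator | None = None) -> dict:
    B, T, F = X.shape
    H = config.hidden_size
    xs = [Tensor(X[:, t, :]) for t in range(T)]
    last = _gru_direction(params, xs, "f", H)[-1]
    if bidirectional:
        last_b = _gru_direction(params, xs[::-1], "b", H)[-1]
        last = concat([last, last_b], axis=1)
    if drop_rng is not None and config.dropout > 0:
        keep = 1.0 - config.dropout
        last = last * Tensor(drop_rng.random(last.shape) < keep) * (1.0 / keep)
    logit = (last @ params["Wo"])[:, 0] + params["bo"]
    return {"logit": logit}


class BaselineModel:
    """GRU / BGRU (last hidden -> linear) or sklearn logistic baseline."""

    def __init__(self, kind: str, config: TitvConfig, T: int, F: int):
        if kind not in ("logistic", "gru", "bgru"):
            raise ValueError(f"unknown baseline kind {kind!r}")
        self.kind = kind
        self.config = config
        self.T, self.F = T, F
        self.params: dict[str, Tensor] | None = None
        self.sk_model: LogisticRegression | None = None
        self.history: list[dict] = []

    @property
    def n_parameters(self) -> int:
        if self.kind == "logistic":
            return self.T * self.F + 1
        return sum(t.data.size for t in self.params.values())

    def predict_proba(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        if self.kind == "logistic":
            return self.sk_model.predict_proba(X.reshape(len(X), -1))[:, 1]
        g = _gru_graph(self.params, X, M, self.config, self.kind == "bgru")
        return sigmoid_np(g["logit"].data)


def fit_baseline(kind: str,
                 train: tuple[np.ndarray, np.ndarray, np.ndarray],
                 valid: tuple[np.ndarray, np.ndarray, np.ndarray],
                 config: TitvConfig | None = None) -> BaselineModel:
    """Fit one of the comparison models with the shared protocol."""
    config = config or TitvConfig()
    Xtr, Mtr, ytr = train
    _, T, F = Xtr.shape
    model = BaselineModel(kind, config, T, F)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training labels must contain both classes")
    if kind == "logistic":
        n_pos = int(ytr.sum())
        w_pos = (len(ytr) - n_pos) / n_pos \
            if config.positive_class_weight == "auto" \
            else float(config.positive_class_weight)
        clf = LogisticRegression(max_iter=2000, C=1.0,
                                 class_weight={0: 1.0, 1: w_pos},
                                 random_state=config.seed)
        clf.fit(Xtr.reshape(len(Xtr), -1), ytr)
        model.sk_model = clf
        return model
    bidirectional = kind == "bgru"
    rng = np.random.default_rng(config.seed)
    params = init_gru_params(T, F, config, bidirectional, rng)

    def graph_fn(p, X, M, drop_rng):
        return _gru_graph(p, X, M, config, bidirectional, drop_rng)

    model.params = params
    model.history = _train_loop(graph_fn, params, train, valid, config)
    return model
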