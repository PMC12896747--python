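"""A small dual-branch 1D Conv–Attention–MLP network in NumPy.

The network treats a feature vector as a 1-D signal. A convolutional branch
(two conv layers with 64 and 256 filters, kernel sizes 5 and 3) extracts
local patterns, recalibrated by a squeeze-and-excitation channel-attention
block and a convolutional spatial-attention gate, then collapsed by global
max pooling. A parallel MLP branch with a residual connection learns global
patterns from the raw vector. The two branches are fused by a dense layer
feeding a softmax output — class probabilities for classification, or a
composition simplex (fractions summing to 1) for quantification.

Training uses Adam with mean-squared-error or cross-entropy loss, learning
rate decay on validation plateau, and early stopping with best-weight
restore. Everything is explicit forward/backward NumPy; gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvAttentionNet"]


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv1d_forward(x, w, b, k):
    """x: (B, C, L); w: (C*k, F); same padding. Returns (out (B,F,L),
    patches (B, L, C*k)) — patches are cached for the backward pass."""
    B, C, L = x.shape
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, k - 1 - p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # B,C,L,k
    patches = win.transpose(0, 2, 1, 3).reshape(B, L, C * k)
    out = patches @ w + b                      # (B, L, F)
    return out.transpose(0, 2, 1), patches


def _conv1d_backward(dout, patches, w, k, c_in, l_out):
    """dout: (B, F, L). Returns (dx (B,C,L), dw, db)."""
    B = dout.shape[0]
    dflat = dout.transpose(0, 2, 1)            # (B, L, F)
    dw = np.einsum("blc,blf->cf", patches, dflat)
    db = dflat.sum(axis=(0, 1))
    dpatch = (dflat @ w.T).reshape(B, l_out, c_in, k)
    p = (k - 1) // 2
    dxp = np.zeros((B, c_in, l_out + k - 1))
    for j in range(k):
        dxp[:, :, j:j + l_out] += dpatch[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, p:p + l_out], dw, db


class ConvAttentionNet:
    """Dual-branch Conv–Attention–MLP with a softmax head.

    Parameters
    ----------
    input_len : length of the input feature vector.
    n_outputs : number of softmax outputs (classes, or 5 oil fractions).
    loss : "ce" (cross-entropy, classification) or "mse" (regression on the
        softmax simplex).
    """

    K1, K2, KSP = 5, 3, 7
    F1, F2 = 64, 256
    SE_REDUCTION = 8
    MLP_HIDDEN = 64
    FUSE_HIDDEN = 64

    def __init__(self, input_len: int, n_outputs: int, loss: str = "ce",
                 seed: int = 42):
        if input_len < max(self.K1, self.K2):
            raise ValueError(
                f"input length {input_len} shorter than kernel size")
        if loss not in ("ce", "mse"):
            raise ValueError("loss must be 'ce' or 'mse'")
        self.input_len = int(input_len)
        self.n_outputs = int(n_outputs)
        self.loss = loss
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        L, F1, F2 = self.input_len, self.F1, self.F2
        se = max(F2 // self.SE_REDUCTION, 4)
        H, FH = self.MLP_HIDDEN, self.FUSE_HIDDEN

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "Wc1": he((1 * self.K1, F1), self.K1), "bc1": np.zeros(F1),
            "Wc2": he((F1 * self.K2, F2), F1 * self.K2), "bc2": np.zeros(F2),
            "Ws1": he((F2, se), F2), "bs1": np.zeros(se),
            "Ws2": he((se, F2), se), "bs2": np.zeros(F2),
            "Wsp": he((2 * self.KSP, 1), 2 * self.KSP), "bsp": np.zeros(1),
            "Wm1": he((L, H), L), "bm1": np.zeros(H),
            "Wr1": he((H, H), H), "br1": np.zeros(H),
            "Wr2": he((H, H), H), "br2": np.zeros(H),
            "Wf1": he((F2 + H, FH), F2 + H), "bf1": np.zeros(FH),
            "Wo": rng.normal(0.0, np.sqrt(1.0 / FH),
                             size=(FH, self.n_outputs)),
            "bo": np.zeros(self.n_outputs),
        }
        self.history: dict[str, list[float]] = {"train_loss": [],
                                                "val_loss": [], "lr": []}

    # -- forward ----------------------------------------------------------

    def _forward(self, x, cache=None):
        P = self.params
        B, L = x.shape
        want = cache is not None

        x3 = x[:, None, :]
        c1, pat1 = _conv1d_forward(x3, P["Wc1"], P["bc1"], self.K1)
        a1 = _relu(c1)
        c2, pat2 = _conv1d_forward(a1, P["Wc2"], P["bc2"], self.K2)
        a2 = _relu(c2)
        # channel attention (squeeze-and-excitation)
        gap = a2.mean(axis=2)
        ps1 = gap @ P["Ws1"] + P["bs1"]
        s1 = _relu(ps1)
        ps2 = s1 @ P["Ws2"] + P["bs2"]
        s2 = _sigmoid(ps2)
        hse = a2 * s2[:, :, None]
        # spatial attention
        ch_mean = hse.mean(axis=1)
        ch_idx = hse.argmax(axis=1)                      # (B, L)
        ch_max = np.take_along_axis(hse, ch_idx[:, None, :], axis=1)[:, 0, :]
        m = np.stack([ch_mean, ch_max], axis=1)          # (B, 2, L)
        gpre, patsp = _conv1d_forward(m, P["Wsp"], P["bsp"], self.KSP)
        g = _sigmoid(gpre)
        hsp = hse * g
        pool_idx = hsp.argmax(axis=2)                    # (B, F2)
        pooled = np.take_along_axis(hsp, pool_idx[:, :, None], axis=2)[:, :, 0]
        # MLP branch with residual connection
        pm1 = x @ P["Wm1"] + P["bm1"]
        m1 = _relu(pm1)
        pr1 = m1 @ P["Wr1"] + P["br1"]
        r1 = _relu(pr1)
        r2 = m1 + r1 @ P["Wr2"] + P["br2"]
        m2 = _relu(r2)
        # fusion head
        f = np.concatenate([pooled, m2], axis=1)
        pf1 = f @ P["Wf1"] + P["bf1"]
        f1 = _relu(pf1)
        z = f1 @ P["Wo"] + P["bo"]
        p = _softmax(z)
        if want:
            cache.update(x=x, c1=c1, pat1=pat1, a1=a1, c2=c2, pat2=pat2,
                         a2=a2, gap=gap, ps1=ps1, s1=s1, s2=s2, hse=hse,
                         ch_idx=ch_idx, m=m, patsp=patsp, gpre=gpre, g=g,
                         hsp=hsp, pool_idx=pool_idx, pooled=pooled,
                         pm1=pm1, m1=m1, pr1=pr1, r1=r1, r2=r2, m2=m2,
                         f=f, pf1=pf1, f1=f1, z=z, p=p)
        return p

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax outputs, deterministic given fixed weights."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.input_len:
            raise ValueError(
                f"expected (n, {self.input_len}) input, got {x.shape}")
        if x.shape[0] == 0:
            return np.zeros((0, self.n_outputs))
        chunks = [self._forward(x[i:i + batch_size])
                  for i in range(0, x.shape[0], batch_size)]
        return np.vstack(chunks)

    # -- loss + backward --------------------------------------------------

    def loss_value(self, p, y):
        if self.loss == "ce":
            eps = 1e-12
            return float(-(y * np.log(p + eps)).sum() / p.shape[0])
        return float(((p - y) ** 2).sum() / p.shape[0])

    def _loss_grads(self, x, y):
        """Loss and parameter gradients for a batch (y one-hot / fractions)."""
        cache: dict = {}
        p = self._forward(x, cache)
        B = x.shape[0]
        loss = self.loss_value(p, y)
        if self.loss == "ce":
            dz = (p - y) / B
        else:
            gp = 2.0 * (p - y) / B
            dz = p * (gp - (gp * p).sum(axis=1, keepdims=True))
        P, c = self.params, cache
        G = {}
        # fusion head
        G["Wo"] = c["f1"].T @ dz
        G["bo"] = dz.sum(axis=0)
        df1 = dz @ P["Wo"].T
        dpf1 = df1 * (c["pf1"] > 0)
        G["Wf1"] = c["f"].T @ dpf1
        G["bf1"] = dpf1.sum(axis=0)
        df = dpf1 @ P["Wf1"].T
        dpooled = df[:, :self.F2]
        dm2 = df[:, self.F2:]
        # MLP branch
        dr2 = dm2 * (c["r2"] > 0)
        G["Wr2"] = c["r1"].T @ dr2
        G["br2"] = dr2.sum(axis=0)
        dr1 = dr2 @ P["Wr2"].T
        dpr1 = dr1 * (c["pr1"] > 0)
        G["Wr1"] = c["m1"].T @ dpr1
        G["br1"] = dpr1.sum(axis=0)
        dm1 = dpr1 @ P["Wr1"].T + dr2            # residual skip
        dpm1 = dm1 * (c["pm1"] > 0)
        G["Wm1"] = c["x"].T @ dpm1
        G["bm1"] = dpm1.sum(axis=0)
        # conv branch: global max pool
        dhsp = np.zeros_like(c["hsp"])
        np.put_along_axis(dhsp, c["pool_idx"][:, :, None],
                          dpooled[:, :, None], axis=2)
        # spatial attention
        dhse = dhsp * c["g"]
        dg = (dhsp * c["hse"]).sum(axis=1, keepdims=True)
        dgpre = dg * c["g"] * (1.0 - c["g"])
        dmix, G["Wsp"], G["bsp"] = _conv1d_backward(
            dgpre, c["patsp"], P["Wsp"], self.KSP, 2, x.shape[1])
        dhse += dmix[:, 0][:, None, :] / self.F2
        dmax = np.zeros_like(dhse)
        np.put_along_axis(dmax, c["ch_idx"][:, None, :],
                          dmix[:, 1][:, None, :], axis=1)
        dhse += dmax
        # channel attention
        da2 = dhse * c["s2"][:, :, None]
        ds2 = (dhse * c["a2"]).sum(axis=2)
        dps2 = ds2 * c["s2"] * (1.0 - c["s2"])
        G["Ws2"] = c["s1"].T @ dps2
        G["bs2"] = dps2.sum(axis=0)
        ds1 = dps2 @ P["Ws2"].T
        dps1 = ds1 * (c["ps1"] > 0)
        G["Ws1"] = c["gap"].T @ dps1
        G["bs1"] = dps1.sum(axis=0)
        dgap = dps1 @ P["Ws1"].T
        da2 += dgap[:, :, None] / x.shape[1]
        # conv stack
        dc2 = da2 * (c["c2"] > 0)
        da1, G["Wc2"], G["bc2"] = _conv1d_backward(
            dc2, c["pat2"], P["Wc2"], self.K2, self.F1, x.shape[1])
        dc1 = da1 * (c["c1"] > 0)
        _, G["Wc1"], G["bc1"] = _conv1d_backward(
            dc1, c["pat1"], P["Wc1"], self.K1, 1, x.shape[1])
        return loss, G

    # -- training ---------------------------------------------------------

    def fit(self, x, y, x_val=None, y_val=None, *, epochs: int = 200,
            batch_size: int = 32, lr: float = 1e-3, patience: int = 20,
            lr_patience: int = 10, lr_factor: float = 0.5,
            min_lr: float = 1e-5, seed: int | None = None,
            verbose: bool = False):
        """Adam training with early stopping on validation loss.

        Without a validation set the training loss drives the plateau and
        stopping logic. Best weights (lowest monitored loss) are restored
        at the end. Deterministic for a fixed seed.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        mstate = {k: np.zeros_like(v) for k, v in self.params.items()}
        vstate = {k: np.zeros_like(v) for k, v in self.params.items()}
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stale = lr_stale = 0
        n = x.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                loss, grads = self._loss_grads(x[idx], y[idx])
                ep_loss += loss * idx.size
                step += 1
                for k in self.params:
                    g = grads[k]
                    mstate[k] = beta1 * mstate[k] + (1 - beta1) * g
                    vstate[k] = beta2 * vstate[k] + (1 - beta2) * g * g
                    mh = mstate[k] / (1 - beta1 ** step)
                    vh = vstate[k] / (1 - beta2 ** step)
                    self.params[k] -= lr * mh / (np.sqrt(vh) + eps)
            ep_loss /= n
            if x_val is not None and len(x_val):
                monitored = self.loss_value(self.predict_proba(x_val),
                                            np.asarray(y_val, dtype=float))
            else:
                monitored = ep_loss
            self.history["train_loss"].append(ep_loss)
            self.history["val_loss"].append(monitored)
            self.history["lr"].append(lr)
            if verbose:
                print(f"epoch {epoch:3d} train {ep_loss:.6f} "
                      f"monitor {monitored:.6f} lr {lr:g}")
            if monitored < best_loss - 1e-9:
                best_loss = monitored
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = lr_stale = 0
            else:
                stale += 1
                lr_stale += 1
                if lr_stale >= lr_patience and lr > min_lr:
                    lr = max(lr * lr_factor, min_lr)
                    lr_stale = 0
                if stale >= patience:
                    break
        self.params = best_params
        return self
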