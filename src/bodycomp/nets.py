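"""A compact, dependency-free CNN engine for small 2D/3D segmentation nets.

The two networks in this package (a 3D encoder-decoder for disk-blob
localization and a 2D competitive dense network for tissue segmentation) are
small enough to train on CPU for synthetic phantoms, so the engine is written
directly on numpy:

* convolutions are im2col + BLAS matmul, stride 1, 'same' padding, odd kernels;
* downsampling is 2x mean pooling, upsampling is 2x nearest-neighbour;
* feature merging at dense-block and skip junctions is either competitive
  (element-wise maximum, "maxout") or plain concatenation;
* the loss is cross-entropy plus soft-Dice over foreground classes;
* optimisation is Adam.

Everything is float32 and fully deterministic for a fixed numpy Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv",
    "SegNet",
    "Adam",
    "maxout",
    "maxout_backward",
    "softmax",
    "ce_dice_loss",
    "sliding_window_probs",
    "pad_to_multiple",
]


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def maxout(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Competitive merge: element-wise maximum of two equal-shape feature maps."""
    if a.shape != b.shape:
        raise ValueError(f"maxout requires equal shapes, got {a.shape} vs {b.shape}")
    return np.maximum(a, b)


def maxout_backward(a, b, gy):
    """Route the gradient to the winning operand (ties go to the first)."""
    take_a = a >= b
    return gy * take_a, gy * ~take_a


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def ce_dice_loss(logits: np.ndarray, target: np.ndarray,
                 dice_classes=None, eps: float = 1e-5,
                 class_weights=None):
    """Cross-entropy + soft-Dice loss and its gradient w.r.t. the logits.

    Parameters
    ----------
    logits : (N, C, *spatial) float array
    target : (N, *spatial) integer class map
    dice_classes : iterable of int, optional
        Classes entering the soft-Dice term (defaults to all non-zero classes).
    class_weights : (C,) array, optional
        Per-class weights for the CE term (counteracts extreme class
        imbalance, e.g. a tiny foreground blob); normalized by the total
        pixel weight.

    Returns
    -------
    loss : float
    dlogits : array like ``logits``
    """
    n, c = logits.shape[:2]
    p = softmax(logits, axis=1)
    flat_p = p.reshape(n, c, -1)
    npx = flat_p.shape[-1]
    onehot = np.zeros_like(flat_p)
    idx = target.reshape(n, -1)
    np.put_along_axis(onehot, idx[:, None, :], 1.0, axis=1)

    logp = -np.log(np.take_along_axis(flat_p, idx[:, None, :], axis=1) + 1e-12)
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float32)[idx]  # (n, npx)
        total = float(w.sum())
        ce = float((w[:, None, :] * logp).sum()) / total
        w_pix = (w / total)[:, None, :]
    else:
        total = n * npx
        ce = float(logp.sum()) / total
        w_pix = 1.0 / total
    g_p = np.zeros_like(flat_p)  # dL/dp

    if dice_classes is None:
        dice_classes = range(1, c)
    dice_classes = list(dice_classes)
    dice_loss = 0.0
    for cc in dice_classes:
        pc = flat_p[:, cc, :]
        gc = onehot[:, cc, :]
        inter = (pc * gc).sum()
        denom = pc.sum() + gc.sum()
        a_ = 2.0 * inter + eps
        b_ = denom + eps
        dice_loss += 1.0 - a_ / b_
        # d(1 - a/b)/dpc = -(2 g b - a) / b^2
        g_p[:, cc, :] += -(2.0 * gc * b_ - a_) / (b_ * b_) / len(dice_classes)
    dice_loss /= len(dice_classes)

    # chain through softmax for the dice part; CE has the closed-form p - y
    dot = (g_p * flat_p).sum(axis=1, keepdims=True)
    dlogits = flat_p * (g_p - dot) + (flat_p - onehot) * w_pix
    return float(ce + dice_loss), dlogits.reshape(logits.shape).astype(np.float32)


def pad_to_multiple(x: np.ndarray, mult: int, nd: int, value: float = 0.0):
    """Pad the last ``nd`` axes of ``x`` up to a multiple of ``mult``.

    Returns the padded array and the original spatial shape (for cropping back).
    """
    sp = x.shape[-nd:]
    pads = [(0, 0)] * (x.ndim - nd)
    for s in sp:
        extra = (-s) % mult
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(x, pads, constant_values=value), sp, pads[-nd:]


def crop_back(x: np.ndarray, orig_shape, pads):
    sl = [slice(None)] * (x.ndim - len(orig_shape))
    for s, (lo, _hi) in zip(orig_shape, pads):
        sl.append(slice(lo, lo + s))
    return x[tuple(sl)]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv:
    """ND convolution (stride 1, 'same' padding, odd kernel) + optional ReLU."""

    def __init__(self, cin, cout, k, nd, rng, relu=True):
        if k % 2 == 0:
            raise ValueError("only odd kernels are supported")
        self.cin, self.cout, self.k, self.nd, self.relu = cin, cout, k, nd, relu
        fan_in = cin * k ** nd
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin) + (k,) * nd).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None
        self._mask = None

    def _cols(self, x, cin):
        """Kernel-offset gather: (N, C, *sp) -> (N, C*k^nd, P), P = prod(sp).

        Built by looping over the k^nd kernel offsets and block-copying the
        shifted padded array — far cheaper on CPU than a strided
        sliding-window transpose.
        """
        k, nd = self.k, self.nd
        p = k // 2
        pad = ((0, 0), (0, 0)) + ((p, p),) * nd
        xp = np.pad(x, pad)
        n = x.shape[0]
        sp = x.shape[2:]
        P = int(np.prod(sp))
        K = k ** nd
        cols = np.empty((n, cin, K, P), dtype=np.float32)
        for flat in range(K):
            off = np.unravel_index(flat, (k,) * nd)
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, sp))
            cols[:, :, flat, :] = xp[sl].reshape(n, cin, P)
        return cols.reshape(n, cin * K, P)

    def _apply(self, x, Wmat, bias, cout):
        cin = Wmat.shape[1] // self.k ** self.nd
        cols = self._cols(x, cin)
        y = np.matmul(Wmat, cols)  # (N, cout, P)
        if bias is not None:
            y += bias[:, None]
        return y.reshape((x.shape[0], cout) + x.shape[2:])

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols = self._cols(x, self.cin)  # (N, CK, P)
        Wmat = self.W.reshape(self.cout, -1)
        y = np.matmul(Wmat, cols)
        y += self.b[:, None]
        y = y.reshape((x.shape[0], self.cout) + x.shape[2:])
        if train:
            self._cols_cache = cols  # reused for the weight gradient
            self._sp = x.shape[2:]
        if self.relu:
            mask = y > 0
            y = y * mask
            if train:
                self._mask = mask
        return y

    def backward(self, gy):
        if self.relu:
            gy = gy * self._mask
        n = gy.shape[0]
        g = np.ascontiguousarray(gy, dtype=np.float32).reshape(n, self.cout, -1)
        cols = self._cols_cache
        gWmat = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
        self.gW += gWmat.reshape(self.W.shape)
        self.gb += g.sum(axis=(0, 2))
        # input gradient = 'same' correlation of gy with the flipped, transposed kernel
        Wf = self.W
        for ax in range(2, 2 + self.nd):
            Wf = np.flip(Wf, axis=ax)
        Wf = np.swapaxes(Wf, 0, 1)  # (cin, cout, *k)
        gx = self._apply(gy.reshape((n, self.cout) + self._sp),
                         Wf.reshape(self.cin, -1), None, self.cin)
        self._cols_cache = None
        self._mask = None
        return gx

    def zero_grad(self):
        self.gW[:] = 0
        self.gb[:] = 0

    def n_params(self):
        return self.W.size + self.b.size


def _avgpool(x, nd):
    for ax in range(x.ndim - nd, x.ndim):
        if x.shape[ax] % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
    sh = x.shape[:2]
    out = x
    for ax in range(2, 2 + nd):
        s = out.shape
        out = out.reshape(s[:ax] + (s[ax] // 2, 2) + s[ax + 1:]).mean(axis=ax + 1)
    return out


def _avgpool_backward(gy, nd):
    out = gy
    for ax in range(2, 2 + nd):
        out = np.repeat(out, 2, axis=ax)
    return out / (2 ** nd)


def _upsample(x, nd):
    out = x
    for ax in range(2, 2 + nd):
        out = np.repeat(out, 2, axis=ax)
    return out


def _upsample_backward(gy, nd):
    out = gy
    for ax in range(2, 2 + nd):
        s = out.shape
        out = out.reshape(s[:ax] + (s[ax] // 2, 2) + s[ax + 1:]).sum(axis=ax + 1)
    return out


# ---------------------------------------------------------------------------
# blocks and the encoder-decoder
# ---------------------------------------------------------------------------

class _Block:
    """A block of ``layers`` convolutions.

    ``style='chain'``: plain conv->conv (U-Net style).
    ``style='dense'``: competitive dense connectivity — each layer sees the
    running merge of all previous outputs; merging is element-wise maximum
    when ``merge='maxout'`` and channel concatenation (followed by a 1x1
    transition back to the block width, so output shape is merge-invariant)
    when ``merge='concat'``.
    """

    def __init__(self, cin, width, layers, k, nd, rng, style, merge):
        self.style, self.merge, self.nd, self.width = style, merge, nd, width
        self.convs = []
        if style == "chain":
            c = cin
            for _ in range(layers):
                self.convs.append(Conv(c, width, k, nd, rng))
                c = width
            self.transition = None
        else:
            self.convs.append(Conv(cin, width, k, nd, rng))
            for i in range(1, layers):
                c_in = width if merge == "maxout" else i * width
                self.convs.append(Conv(c_in, width, k, nd, rng))
            if merge == "concat":
                # restore block width after concatenation so downstream shape
                # does not depend on the merge mode (controlled ablation)
                self.transition = Conv(layers * width, width, 1, nd, rng, relu=False)
            else:
                self.transition = None

    def all_convs(self):
        out = list(self.convs)
        if self.transition is not None:
            out.append(self.transition)
        return out

    def forward(self, x, train=False):
        if self.style == "chain":
            h = x
            for conv in self.convs:
                h = conv.forward(h, train)
            return h
        h = self.convs[0].forward(x, train)
        if self.merge == "maxout":
            # running element-wise maximum == competitive merge of all
            # previous features (max is associative)
            m = h
            merges = []
            for conv in self.convs[1:]:
                f = conv.forward(m, train)
                if train:
                    merges.append((m, f))
                m = maxout(m, f)
            self._merges = merges if train else None
            return m
        feats = [h]
        for conv in self.convs[1:]:
            f = conv.forward(np.concatenate(feats, axis=1), train)
            feats.append(f)
        out = self.transition.forward(np.concatenate(feats, axis=1), train)
        self._nfeats = len(feats)
        return out

    def backward(self, gy):
        if self.style == "chain":
            g = gy
            for conv in reversed(self.convs):
                g = conv.backward(g)
            return g
        if self.merge == "maxout":
            g = gy
            gm_acc = None
            for conv, (m, f) in zip(reversed(self.convs[1:]), reversed(self._merges)):
                gm, gf = maxout_backward(m, f, g)
                g_in = conv.backward(gf)
                g = gm + g_in
            self._merges = None
            return self.convs[0].backward(g)
        gcat = self.transition.backward(gy)
        w = self.width
        gf = [gcat[:, i * w:(i + 1) * w].copy() for i in range(self._nfeats)]
        for i in range(self._nfeats - 1, 0, -1):
            gin = self.convs[i].backward(gf[i])  # grad w.r.t. concat(f0..f_{i-1})
            for j in range(i):
                gf[j] += gin[:, j * w:(j + 1) * w]
        return self.convs[0].backward(gf[0])


class SegNet:
    """Small 2D/3D encoder-decoder segmentation network.

    Parameters
    ----------
    nd : {2, 3}
        Spatial dimensionality.
    in_ch, n_classes : int
    widths : sequence of int
        Channel width per resolution level, shallow -> deep;
        ``len(widths) - 1`` poolings; input spatial dims must be divisible by
        ``2 ** (len(widths) - 1)``.
    block_style : {'chain', 'dense'}
    merge : {'maxout', 'concat'}
        Merge rule at dense-block and skip junctions (dense style); 'chain'
        style always concatenates at skips (classic U-Net).
    """

    def __init__(self, nd, in_ch, n_classes, widths, rng,
                 block_style="chain", merge="concat",
                 block_layers=2, kernel=3):
        self.nd = nd
        self.n_classes = n_classes
        self.widths = list(widths)
        self.block_style = block_style
        self.merge = merge
        L = len(self.widths)
        self.enc = []
        c = in_ch
        for i in range(L):
            self.enc.append(_Block(c, self.widths[i], block_layers, kernel, nd,
                                   rng, block_style, merge))
            c = self.widths[i]
        self.up_reduce = []
        self.dec = []
        self.skip_transition = []
        for i in range(L - 2, -1, -1):
            w = self.widths[i]
            self.up_reduce.append(Conv(self.widths[i + 1], w, kernel, nd, rng))
            skip_is_merged = block_style == "dense" and merge == "maxout"
            if skip_is_merged:
                dec_in = w
                self.skip_transition.append(None)
            elif block_style == "dense":  # dense + concat ablation
                self.skip_transition.append(Conv(2 * w, w, 1, nd, rng, relu=False))
                dec_in = w
            else:  # chain: classic concat absorbed by the block's first conv
                self.skip_transition.append(None)
                dec_in = 2 * w
            self.dec.append(_Block(dec_in, w, block_layers, kernel, nd, rng,
                                   block_style, merge))
        self.final = Conv(self.widths[0], n_classes, 1, nd, rng, relu=False)

    # -- plumbing ----------------------------------------------------------
    def convs(self):
        out = []
        for b in self.enc:
            out += b.all_convs()
        for c in self.up_reduce:
            out.append(c)
        for c in self.skip_transition:
            if c is not None:
                out.append(c)
        for b in self.dec:
            out += b.all_convs()
        out.append(self.final)
        return out

    def n_params(self):
        return sum(c.n_params() for c in self.convs())

    def zero_grad(self):
        for c in self.convs():
            c.zero_grad()

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train=False):
        L = len(self.widths)
        skips = []
        h = x
        for i in range(L):
            h = self.enc[i].forward(h, train)
            if i < L - 1:
                skips.append(h)
                h = _avgpool(h, self.nd)
        self._merge_cache = []
        for j, i in enumerate(range(L - 2, -1, -1)):
            h = _upsample(h, self.nd)
            h = self.up_reduce[j].forward(h, train)
            skip = skips[i]
            if self.block_style == "dense" and self.merge == "maxout":
                if train:
                    self._merge_cache.append((h, skip))
                h = maxout(h, skip)
            else:
                h = np.concatenate([h, skip], axis=1)
                if self.skip_transition[j] is not None:
                    h = self.skip_transition[j].forward(h, train)
            h = self.dec[j].forward(h, train)
        return self.final.forward(h, train)

    def backward(self, gy):
        L = len(self.widths)
        g = self.final.backward(gy)
        gskips = [None] * (L - 1)
        mc = list(self._merge_cache)
        for j in range(L - 2, -1, -1):
            i = L - 2 - j
            g = self.dec[j].backward(g)
            if self.block_style == "dense" and self.merge == "maxout":
                up_h, skip = mc.pop()
                gu, gs = maxout_backward(up_h, skip, g)
            else:
                if self.skip_transition[j] is not None:
                    g = self.skip_transition[j].backward(g)
                w = self.up_reduce[j].cout
                gu, gs = g[:, :w], g[:, w:]
            gskips[i] = gs
            g = self.up_reduce[j].backward(gu)
            g = _upsample_backward(g, self.nd)
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                g = _avgpool_backward(g, self.nd)
                g = g + gskips[i]
            g = self.enc[i].backward(g)
        self._merge_cache = []
        return g

    def predict_probs(self, x):
        """Softmax probabilities for a batch, padding spatial dims as needed."""
        mult = 2 ** (len(self.widths) - 1)
        xp, orig, pads = pad_to_multiple(x, mult, self.nd,
                                         value=float(x.min()) if x.size else 0.0)
        logits = self.forward(xp, train=False)
        probs = softmax(logits, axis=1)
        return crop_back(probs, orig, [(p[0], p[1]) for p in pads])


class Adam:
    def __init__(self, net: SegNet, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.convs = net.convs()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [
            (np.zeros_like(c.W), np.zeros_like(c.W),
             np.zeros_like(c.b), np.zeros_like(c.b))
            for c in self.convs
        ]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for c, (mW, vW, mb, vb) in zip(self.convs, self.state):
            for p, g, m, v in ((c.W, c.gW, mW, vW), (c.b, c.gb, mb, vb)):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


# ---------------------------------------------------------------------------
# sliding-window inference
# ---------------------------------------------------------------------------

def _window_starts(size, patch, step):
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, step))
    starts.append(size - patch)
    return sorted(set(starts))


def _gaussian_importance(patch_shape):
    grids = []
    for s in patch_shape:
        x = np.arange(s) - (s - 1) / 2.0
        grids.append(np.exp(-(x ** 2) / (2 * (s / 4.0) ** 2)))
    w = grids[0]
    for g in grids[1:]:
        w = np.multiply.outer(w, g)
    return (w + 1e-3).astype(np.float32)


def sliding_window_probs(net: SegNet, volume: np.ndarray, patch,
                         overlap: float = 0.5) -> np.ndarray:
    """Tiled inference with Gaussian-weighted fusion of overlapping windows.

    ``volume`` is a single (C-less) spatial array; returns ``(n_classes, *shape)``
    softmax probabilities.
    """
    nd = net.nd
    mult = 2 ** (len(net.widths) - 1)
    pad_val = float(volume.min())
    # pad so every axis is pool-divisible; window sizes are then clipped to the
    # (divisible) padded shape and rounded to the pooling multiple
    padded, orig, pads = pad_to_multiple(volume[None, None], mult, nd, value=pad_val)
    vol = padded[0, 0]
    patch = tuple(min(max(mult, (p // mult) * mult), s)
                  for p, s in zip(patch, vol.shape))
    steps = [max(1, int(p * (1 - overlap))) for p in patch]
    acc = np.zeros((net.n_classes,) + vol.shape, dtype=np.float32)
    wacc = np.zeros(vol.shape, dtype=np.float32)
    wmap = _gaussian_importance(patch)
    for zs in _window_starts(vol.shape[0], patch[0], steps[0]):
        for ys in _window_starts(vol.shape[1], patch[1], steps[1]):
            if nd == 3:
                xs_list = _window_starts(vol.shape[2], patch[2], steps[2])
            else:
                xs_list = [None]
            for xs in xs_list:
                sl = (slice(zs, zs + patch[0]), slice(ys, ys + patch[1]))
                if nd == 3:
                    sl = sl + (slice(xs, xs + patch[2]),)
                win = vol[sl]
                logits = net.forward(win[None, None], train=False)
                probs = softmax(logits, axis=1)[0]
                acc[(slice(None),) + sl] += probs * wmap
                wacc[sl] += wmap
    acc /= wacc
    return crop_back(acc[None], orig, [(p[0], p[1]) for p in pads])[0]
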