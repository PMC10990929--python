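"""Independent brute-force (MS-)SSIM oracles: explicit window loops,
literal formula, population statistics. Used by the unit and acceptance
suites; deliberately independent of the package implementation."""

import numpy as np


def ssim_oracle(a, b, window, k1=0.01, k2=0.03, data_range=None):
    """Independent brute-force implementation: explicit loops over every
    valid window, literal formula, population statistics."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    L = data_range if data_range is not None else max(a.max(), b.max())
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    h, w = a.shape
    vals = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            wa = a[i:i + window, j:j + window].ravel()
            wb = b[i:i + window, j:j + window].ravel()
            mu_a, mu_b = wa.mean(), wb.mean()
            var_a = ((wa - mu_a) ** 2).mean()
            var_b = ((wb - mu_b) ** 2).mean()
            cov = ((wa - mu_a) * (wb - mu_b)).mean()
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1)
                           * (var_a + var_b + c2)))
    return float(np.mean(vals))


def msssim_oracle(a, b, window, levels, weights, k1=0.01, k2=0.03,
                  data_range=None):
    """Per-scale brute force: cs terms at fine scales, full SSIM at the
    coarsest; 2x2 block-mean downsampling."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    L = data_range if data_range is not None else max(a.max(), b.max())
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2

    def down(img):
        h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
        c = img[:h, :w]
        return 0.25 * (c[0::2, 0::2] + c[1::2, 0::2]
                       + c[0::2, 1::2] + c[1::2, 1::2])

    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    terms = []
    for lev in range(levels):
        h, w = a.shape
        vals = []
        for i in range(h - window + 1):
            for j in range(w - window + 1):
                wa = a[i:i + window, j:j + window].ravel()
                wb = b[i:i + window, j:j + window].ravel()
                mu_a, mu_b = wa.mean(), wb.mean()
                var_a = ((wa - mu_a) ** 2).mean()
                var_b = ((wb - mu_b) ** 2).mean()
                cov = ((wa - mu_a) * (wb - mu_b)).mean()
                cs = (2 * cov + c2) / (var_a + var_b + c2)
                if lev == levels - 1:
                    lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
                    vals.append(lum * cs)
                else:
                    vals.append(cs)
        terms.append(max(0.0, float(np.mean(vals))))
        if lev < levels - 1:
            a, b = down(a), down(b)
    return float(np.prod(np.asarray(terms) ** weights))
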