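import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight deterministic 64x64 synthetic scenes with masks."""
    from pestseg.synth import SceneSpec, generate_scene

    spec = SceneSpec()
    g = np.random.default_rng(7)
    imgs, masks = [], []
    for _ in range(8):
        im, m = generate_scene(spec, g)
        imgs.append(im)
        masks.append(m)
    return np.stack(imgs), np.stack(masks)


def random_ssm_params(rng, L, D, N):
    from pestseg.ssm import SSMParams

    return SSMParams(
        A_log=rng.normal(0.0, 1.0, (D, N)),
        D_skip=rng.normal(0.0, 1.0, D),
        B=rng.normal(0.0, 1.0, (L, N)),
        C=rng.normal(0.0, 1.0, (L, N)),
        delta=np.abs(rng.normal(0.0, 1.0, (L, D))) + 1e-3,
    )


def unrolled_scan_oracle(seq, params):
    """Brute-force closed form: y_t = C_t . sum_s (prod_r Abar_r) Bbar_s x_s."""
    L, D = seq.shape
    N = params.A_log.shape[1]
    A = -np.exp(params.A_log)
    y = np.zeros((L, D))
    for d in range(D):
        for t in range(L):
            acc = 0.0
            for n in range(N):
                total = 0.0
                for s in range(t + 1):
                    prod = 1.0
                    for r in range(s + 1, t + 1):
                        prod *= np.exp(params.delta[r, d] * A[d, n])
                    total += prod * params.delta[s, d] * params.B[s, n] * seq[s, d]
                acc += params.C[t, n] * total
            y[t, d] = acc + params.D_skip[d] * seq[t, d]
    return y
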