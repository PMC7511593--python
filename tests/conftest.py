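import numpy as np
import pytest

from modmedsem import popgen as pg


@pytest.fixture(scope="session")
def high_rel_spec():
    """Population model: high reliability, b3 = 0.2, normal errors, cor(X,Z)=0."""
    return pg.make_population_spec(pg.DesignCell(n=500, b3=0.2))


@pytest.fixture(scope="session")
def population_theta():
    """Map a PopulationSpec onto a named free-parameter vector factory."""

    def build(spec, param_names, interaction=True):
        idx = {n: i for i, n in enumerate(param_names)}
        theta = np.zeros(len(param_names))
        for label, cols in pg.BLOCKS.items():
            blk = spec.block(label)
            for j, cname in enumerate(cols):
                if j > 0:
                    theta[idx[f"lam_{cname}"]] = blk.loadings[j]
                theta[idx[f"tau_{cname}"]] = blk.intercepts[j]
                theta[idx[f"th_{cname}"]] = blk.error_variances[j]
        s = spec.structural
        values = {
            "a": s.a, "b1": s.b1, "b2": s.b2, "c": s.c,
            "var_x": s.var_X, "var_z": s.var_Z, "cov_xz": s.cov_XZ,
            "resid_m": s.resid_var_M, "resid_y": s.resid_var_Y,
        }
        if interaction and "b3" in idx:
            values["b3"] = s.b3
        for name, val in values.items():
            theta[idx[name]] = val
        return theta

    return build


@pytest.fixture(scope="session")
def dataset_n500(high_rel_spec):
    rng = np.random.default_rng(20240901)
    return pg.generate_dataset(high_rel_spec, 500, rng)
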