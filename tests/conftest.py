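import numpy as np
import pytest

from scaffoldmatch.structure_io import AtomRecord, Residue, Structure
from scaffoldmatch.synthetic import FixtureRecipe, HelixParams, build_hlh


def ca_structure(coords, names=None, structure_id="TEST"):
    """Build a CA-only single-chain Structure from an n x 3 array."""
    coords = np.asarray(coords, dtype=float)
    names = names or ["ALA"] * len(coords)
    residues = [
        Residue(name=names[i], seq_id=i + 1, label_id=i + 1,
                atoms=[AtomRecord(name="CA", element="C", position=coords[i])])
        for i in range(len(coords))
    ]
    return Structure(id=structure_id, chains={"A": residues})


def horn_rmsd(P, Q):
    """Independent superposition oracle: Horn's quaternion eigenvalue method.

    Builds the 4x4 key matrix from the correlation of centered point sets;
    the largest eigenvalue lambda_max gives the minimal residual
    E = sum|P|^2 + sum|Q|^2 - 2 lambda_max, hence the RMSD, without ever
    forming a rotation matrix.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Qc.T @ Pc  # correlation of candidate against reference
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e = (Pc**2).sum() + (Qc**2).sum() - 2.0 * lam
    return float(np.sqrt(max(e, 0.0) / len(P)))


@pytest.fixture
def hlh_clean():
    """Noise-free 10/5/10 helix-loop-helix fixture with two disulfides."""
    recipe = FixtureRecipe(
        helix1=HelixParams(n_res=10),
        loop_len=5,
        helix2=HelixParams(n_res=10),
        cys_positions=(2, 9, 18, 25),
        disulfide_pairs=((1, 4), (2, 3)),
    )
    return build_hlh(recipe)


@pytest.fixture
def random_rigid():
    """Seeded generator of proper rotations and translations."""
    from scipy.spatial.transform import Rotation

    def make(seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-50, 50, 3)
        return R, t

    return make
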