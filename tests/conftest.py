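import numpy as np
import pytest

import lyotraj as lt


@pytest.fixture
def helix():
    return lt.make_ideal_fragment("helix", 12)


@pytest.fixture
def hairpin():
    return lt.make_ideal_fragment("hairpin", 12)


@pytest.fixture
def cg_monomer():
    return lt.make_cg_monomer(n_residues=3, spacing=6.0)


@pytest.fixture
def solvated(helix):
    return lt.make_solvated_fixture(helix, [(2.5, 10), (5.0, 10)], seed=7)


def brute_force_contacts(model, coords=None, cutoff=4.0):
    """O(N^2) all-pairs inter-chain residue contact oracle, with minimum-image
    wrapping when the model carries a box."""
    xyz = model.coords if coords is None else np.asarray(coords, float)
    box = model.box
    residues = [r for r in model.residues()
                if model.atoms[r[2][0]].role == "protein"]
    out = set()
    for p in range(len(residues)):
        cp, rp, ip = residues[p]
        for q in range(p + 1, len(residues)):
            cq, rq, iq = residues[q]
            if cp == cq:
                continue
            best = np.inf
            for i in ip:
                for j in iq:
                    d = xyz[i] - xyz[j]
                    if box is not None:
                        d = d - box.lengths * np.round(d / box.lengths)
                    best = min(best, float(np.linalg.norm(d)))
            if best < cutoff:
                a, b = sorted([(cp, rp), (cq, rq)])
                out.add((a[0], b[0], a[1], b[1]))
    return out


def quaternion_rmsd(mobile, reference):
    """Independent optimal-superposition RMSD via Horn's quaternion method."""
    P = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    Q = np.asarray(reference, float) - np.mean(reference, axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    e2 = (np.sum(P ** 2) + np.sum(Q ** 2) - 2.0 * lam) / len(P)
    return float(np.sqrt(max(e2, 0.0)))
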