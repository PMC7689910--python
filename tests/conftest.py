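import numpy as np
import pandas as pd
import pytest

from fuzzynmr.core_io import ONE_TO_THREE, Sequence, ShiftTable, SpectrometerContext
from fuzzynmr.ensemble import Ensemble


@pytest.fixture(scope="session")
def ctx():
    return SpectrometerContext(freq_1H=700.17)


@pytest.fixture(scope="session")
def preset():
    from fuzzynmr.synthetic_data import p53tad_like

    return p53tad_like()


def make_shift_table(records, protein_id="test", state="free"):
    """records: (residue_index, residue_type, nucleus, shift_ppm) tuples."""
    return ShiftTable(
        protein_id=protein_id,
        state=state,
        rows=pd.DataFrame(
            records,
            columns=["residue_index", "residue_type", "nucleus", "shift_ppm"],
        ),
    )


def make_ensemble(coords, atom_specs):
    """coords: (n_models, n_atoms, 3); atom_specs: (chain, resid, aa1, name, element)."""
    atoms = pd.DataFrame(
        atom_specs,
        columns=["chain", "residue_index", "residue_type", "atom_name", "element"],
    )
    atoms["residue_name"] = [ONE_TO_THREE.get(a, "UNK") for a in atoms.residue_type]
    return Ensemble(coords=np.asarray(coords, dtype=float), atoms=atoms)


def helix_ensemble(n_res=10, n_models=1, phi=-57.0, psi=-47.0, seq=None, jitter=0.0,
                   rng=None):
    """Ideal (or jittered) helical backbone ensemble on a poly-Ala chain."""
    from fuzzynmr.synthetic_data import build_backbone

    seq = seq or Sequence(id="helix", residues="A" * n_res)
    rng = rng or np.random.default_rng(0)
    frames = []
    records = None
    for _ in range(n_models):
        ph = phi + (rng.normal(0, jitter, len(seq)) if jitter else 0.0)
        ps = psi + (rng.normal(0, jitter, len(seq)) if jitter else 0.0)
        xyz, records = build_backbone(np.broadcast_to(ph, (len(seq),)),
                                      np.broadcast_to(ps, (len(seq),)), seq)
        frames.append(xyz)
    specs = [("P", r[0], r[1], r[2], r[3]) for r in records]
    return make_ensemble(np.stack(frames), specs)
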