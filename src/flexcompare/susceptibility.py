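"""Rigidity susceptibility: per-pair variance of the rigidity state over an
ensemble of realizations.

For each pixel (j, k), ``chi_jk = <n_jk**2> - <n_jk>**2`` with unweighted
means over the supplied realizations.  With states bounded in {-1, 0, +1}
this lies in [0, 1] by construction; no gap pixels are ever produced here.
"""

from __future__ import annotations

import numpy as np

from .core import RigidityStateEnsemble, SusceptibilityImage, validate_ensemble

__all__ = ["compute_susceptibility"]


def compute_susceptibility(ens: RigidityStateEnsemble) -> SusceptibilityImage:
    validate_ensemble(ens)
    stack = np.stack(ens.realizations).astype(float)
    mean = stack.mean(axis=0)
    chi = (stack**2).mean(axis=0) - mean**2
    # guard float round-off at the boundaries of [0, 1]
    chi = np.clip(chi, 0.0, 1.0)
    chi = 0.5 * (chi + chi.T)
    img = SusceptibilityImage(protein_id=ens.protein_id, chi=chi)
    img.check_symmetric()
    return img
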