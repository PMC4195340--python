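"""Bundled example datasets."""

from __future__ import annotations

from importlib import resources

from ..data import NMADataset, load_long

#: Registry order of the heart-failure network (A..E in the usual diagram).
HEART_FAILURE_TREATMENTS = [
    "Medical therapy",
    "Cardiac resynchronization",
    "Implantable defibrillator",
    "Combined resynchronization and defibrillator",
    "Amiodarone",
]


def load_heart_failure() -> NMADataset:
    """All-cause mortality network in left-ventricular dysfunction.

    Twelve randomized trials comparing five treatments (medical therapy,
    cardiac resynchronization, implantable defibrillator, combined
    resynchronization and defibrillator, amiodarone): 1,616 deaths among
    8,307 randomized participants, from the published network meta-analysis
    of Lam & Owen (BMJ 2007) widely used as a worked NMA example.  Medical
    therapy — present in 8 of the 12 trials — is the reference treatment.
    """
    path = resources.files(__package__) / "heart_failure_mortality.csv"
    with resources.as_file(path) as p:
        return load_long(
            p,
            treatment_order=HEART_FAILURE_TREATMENTS,
            reference="Medical therapy",
        )
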