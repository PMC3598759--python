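from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pacval.codes import CodeMap

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def codemap() -> CodeMap:
    return CodeMap.default()


def make_hospital_frame(rows: list[dict], n_diag: int = 5) -> pd.DataFrame:
    """Build a hospital table from dicts with woman_id, record_id,
    admission_date and a ``codes`` list (blank-padded to n_diag fields)."""
    out = []
    for r in rows:
        rec = {
            "woman_id": r["woman_id"],
            "record_id": r["record_id"],
            "admission_date": pd.Timestamp(r["admission_date"]),
        }
        codes = list(r["codes"])
        for i in range(1, n_diag + 1):
            rec[f"diag{i}"] = codes[i - 1] if i <= len(codes) else ""
        out.append(rec)
    return pd.DataFrame(out)


def make_registry_frame(rows: list[dict]) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append(
            {
                "woman_id": r["woman_id"],
                "registry_id": r["registry_id"],
                "diagnosis_date": pd.Timestamp(r["diagnosis_date"]),
                "group": r["group"],
                "first_notification_date": pd.Timestamp(
                    r.get("first_notification_date", r["diagnosis_date"])
                ),
            }
        )
    return pd.DataFrame(out)


def make_maternity_frame(rows: list[dict]) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append(
            {
                "woman_id": r["woman_id"],
                "maternity_id": r["maternity_id"],
                "delivery_date": pd.Timestamp(r["delivery_date"]),
                "gestation_weeks": int(r.get("gestation_weeks", 40)),
            }
        )
    return pd.DataFrame(out)


def random_small_cohort(seed: int, n_women: int = 10):
    """Randomised small linked cohort for brute-force oracle comparisons.

    Windows may overlap (no inter-delivery gap is enforced) to stress the
    attribution rule; codes include eligible, secondary and out-of-scope
    entries; registry rows mix incident and prevalent records.
    """
    rng = np.random.default_rng(seed)
    base = pd.Timestamp("2003-01-01")
    code_pool = ["C50.9", "C43.5", "C18.2", "C91.0", "C78.0", "D05.1", "O80",
                 "Z37.0", "C73", "C64"]
    group_pool = ["breast", "melanoma", "colorectal", "lymphohaematopoeitic",
                  "thyroid_endocrine", "urogenital"]
    maternities, hospital, registry = [], [], []
    mat_n = rec_n = reg_n = 0
    for w in range(n_women):
        woman = f"W{w:03d}"
        for _ in range(rng.integers(1, 4)):
            mat_n += 1
            maternities.append(
                {
                    "woman_id": woman,
                    "maternity_id": f"M{mat_n:03d}",
                    "delivery_date": base + pd.Timedelta(
                        days=int(rng.integers(0, 1100))
                    ),
                    "gestation_weeks": int(rng.integers(20, 45)),
                }
            )
        for _ in range(rng.integers(0, 4)):
            rec_n += 1
            n_codes = int(rng.integers(1, 4))
            hospital.append(
                {
                    "woman_id": woman,
                    "record_id": f"{rng.integers(0, 500)}",
                    "admission_date": base + pd.Timedelta(
                        days=int(rng.integers(-300, 1500))
                    ),
                    "codes": [str(rng.choice(code_pool)) for _ in range(n_codes)],
                }
            )
        for _ in range(rng.integers(0, 3)):
            reg_n += 1
            diag = base + pd.Timedelta(days=int(rng.integers(-300, 1500)))
            prevalent = rng.random() < 0.3
            registry.append(
                {
                    "woman_id": woman,
                    "registry_id": f"R{reg_n:03d}",
                    "diagnosis_date": diag,
                    "group": str(rng.choice(group_pool)),
                    "first_notification_date": diag
                    - pd.Timedelta(days=int(rng.integers(200, 3000)))
                    if prevalent
                    else diag,
                }
            )
    return (
        make_maternity_frame(maternities),
        make_hospital_frame(hospital),
        make_registry_frame(registry),
    )
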