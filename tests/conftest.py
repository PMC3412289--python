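import hashlib
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_result():
    """One full desk-scale experiment run shared across tests."""
    from ca1sep.experiment import make_desk_config, run_experiment

    return run_experiment(make_desk_config(seed=1))


def hash_tree(root: Path) -> dict:
    """Relative path -> sha256 of every file under root."""
    out = {}
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
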