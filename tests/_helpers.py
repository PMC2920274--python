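import numpy as np

import conscore as cs


def random_alignment(seed: int, n: int = 8, length: int = 30) -> cs.Alignment:
    """Gap-free random alignment for score cross-checks."""
    rng = np.random.default_rng(seed)
    from conscore.alphabet import AA_ORDER

    rows = ["".join(rng.choice(list(AA_ORDER), size=length)) for _ in range(n)]
    return cs.Alignment(
        id=f"rand{seed}", seq_ids=[f"s{i}" for i in range(n)], sequences=rows
    )
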