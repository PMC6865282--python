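from datetime import datetime, timezone

import pytest

from opichatter.corpus import Post
from opichatter.lexicon import Keyword, Lexicon


def make_post(i, text, label=None, region="R01", ts="2013-06-15T12:00:00+00:00"):
    return Post(
        id=f"p{i}",
        text=text,
        timestamp=ts,
        region_id=region,
        gold_label=label,
    )


@pytest.fixture
def small_lexicon():
    return Lexicon(
        keywords=[
            Keyword("percocet", "prescription", False, {"percoset", "perkocet"}),
            Keyword("oxycodone", "prescription", False, set()),
            Keyword("heroin", "illicit", False, {"herroin"}),
            Keyword("dope", "illicit", True, {"dopee"}),
            Keyword("tar", "illicit", True, set()),
        ]
    )


@pytest.fixture
def posts_factory():
    return make_post
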