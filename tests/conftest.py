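"""Shared fixtures for the pfdd test suite."""

from __future__ import annotations

import pytest

from pfdd.corpus import SocialPost, Source
from pfdd.synth import MockNLIBackend, MockSentimentBackend


@pytest.fixture
def nli_backend():
    return MockNLIBackend()


@pytest.fixture
def sentiment_backend():
    return MockSentimentBackend()


def make_post(post_id="p1", text="hello world", source=Source.FORUM, **kw) -> SocialPost:
    return SocialPost(post_id=post_id, text=text, source=source, **kw)


@pytest.fixture
def post_factory():
    return make_post
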