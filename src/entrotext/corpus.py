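"""In-memory corpus containers shared by I/O, annotation and generation."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Document:
    """One class-labelled text.

    ``tokens``/``tags`` are optional pre-computed annotation streams; when a
    corpus is generated synthetically or loaded with sidecar tag files they are
    populated directly and automatic annotation is bypassed.
    """

    doc_id: str
    class_label: str
    raw_text: str
    tokens: list[str] | None = None
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.raw_text.strip():
            raise ValueError(f"document {self.doc_id!r}: raw_text is empty")
        if self.tokens is not None and self.tags is not None:
            if len(self.tokens) != len(self.tags):
                raise ValueError(
                    f"document {self.doc_id!r}: {len(self.tokens)} tokens but "
                    f"{len(self.tags)} tags"
                )


@dataclass
class Corpus:
    """An ordered collection of documents with distinct class labels."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    @property
    def class_labels(self) -> list[str]:
        """Distinct class labels in first-appearance order."""
        labels: list[str] = []
        for doc in self.documents:
            if doc.class_label not in labels:
                labels.append(doc.class_label)
        return labels

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)
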