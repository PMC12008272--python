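item_id,polarity,text,source
1,ON,"I have a feeling of well-being",quoted
2,ON,"I feel talkative, I want to communicate",quoted
3,ON,"I feel energetic, full of energy",synthetic
4,ON,"I feel confident and sure of myself",synthetic
5,ON,"I feel cheerful, lively and euphoric",synthetic
6,ON,"I feel creative, I have lots of new ideas",synthetic
7,ON,"I feel motivated, I want to be active",synthetic
8,ON,"I feel relaxed and at ease",synthetic
9,ON,"I feel optimistic about the future",synthetic
10,ON,"I feel strong and capable",synthetic
11,OFF,"I have jelly legs, trembling",quoted
12,OFF,"I lack energy for everyday activities",quoted
13,OFF,"I feel low",quoted
14,OFF,"I feel lethargic",quoted
15,OFF,"I feel tired, exhausted and drained",synthetic
16,OFF,"I feel anxious and worried",synthetic
17,OFF,"I cannot relax, I feel tense",synthetic
18,OFF,"I feel sad, heavy and discouraged",synthetic
19,OFF,"I feel listless, I have no initiative",synthetic
20,OFF,"I feel slow and weary, thinking is an effort",synthetic
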