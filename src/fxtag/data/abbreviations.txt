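# Tokens after which a period never ends a sentence (case-insensitive,
# one per line, period included). Single capital letters ("J.") are
# guarded by a built-in rule and need not be listed.
dr.
mr.
mrs.
ms.
vs.
st.
e.g.
i.e.
no.
fig.
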