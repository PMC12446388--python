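# Curated thermal-sensitivity labels per clade group, from published
# electrophysiology.  Groups without data are labeled unknown.
group_id	label
1	unknown
2	unknown
3	unknown
4	unknown
5	unknown
6	heat
7	unknown
8	heat
9	heat
10	unknown
11	heat
12	unknown
13	unknown
14	unknown
15	unknown
16	unknown
17	unknown
18	unknown
19	unknown
20	unknown
21	unknown
22	unknown
23	unknown
24	insensitive
25	cold
26	insensitive
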