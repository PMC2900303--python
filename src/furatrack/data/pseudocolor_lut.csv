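r,g,b
0,0,255
0,3,252
0,6,249
0,9,246
0,12,243
0,15,240
0,18,237
0,21,234
0,24,231
0,27,228
0,30,225
0,33,222
0,36,219
0,39,216
0,42,213
0,45,210
0,48,207
0,51,204
0,54,201
0,57,198
0,60,195
0,63,192
0,66,189
0,69,186
0,72,183
0,75,180
0,78,177
0,81,174
0,84,171
0,87,168
0,90,165
0,93,162
0,96,159
0,99,156
0,102,153
0,105,150
0,108,147
0,111,144
0,114,141
0,117,138
0,120,135
0,123,132
0,126,129
0,129,126
0,132,123
0,135,120
0,138,117
0,141,114
0,144,111
0,147,108
0,150,105
0,153,102
0,156,99
0,159,96
0,162,93
0,165,90
0,168,87
0,171,84
0,174,81
0,177,78
0,180,75
0,183,72
0,186,69
0,189,66
0,192,63
0,195,60
0,198,57
0,201,54
0,204,51
0,207,48
0,210,45
0,213,42
0,216,39
0,219,36
0,222,33
0,225,30
0,228,27
0,231,24
0,234,21
0,237,18
0,240,15
0,243,12
0,246,9
0,249,6
0,252,3
0,255,0
3,255,0
6,255,0
9,255,0
12,255,0
15,255,0
18,255,0
21,255,0
24,255,0
27,255,0
30,255,0
33,255,0
36,255,0
39,255,0
42,255,0
45,255,0
48,255,0
51,255,0
54,255,0
57,255,0
60,255,0
63,255,0
66,255,0
69,255,0
72,255,0
75,255,0
78,255,0
81,255,0
84,255,0
87,255,0
90,255,0
93,255,0
96,255,0
99,255,0
102,255,0
105,255,0
108,255,0
111,255,0
114,255,0
117,255,0
120,255,0
123,255,0
126,255,0
129,255,0
132,255,0
135,255,0
138,255,0
141,255,0
144,255,0
147,255,0
150,255,0
153,255,0
156,255,0
159,255,0
162,255,0
165,255,0
168,255,0
171,255,0
174,255,0
177,255,0
180,255,0
183,255,0
186,255,0
189,255,0
192,255,0
195,255,0
198,255,0
201,255,0
204,255,0
207,255,0
210,255,0
213,255,0
216,255,0
219,255,0
222,255,0
225,255,0
228,255,0
231,255,0
234,255,0
237,255,0
240,255,0
243,255,0
246,255,0
249,255,0
252,255,0
255,255,0
255,252,0
255,249,0
255,246,0
255,243,0
255,240,0
255,237,0
255,234,0
255,231,0
255,228,0
255,225,0
255,222,0
255,219,0
255,216,0
255,213,0
255,210,0
255,207,0
255,204,0
255,201,0
255,198,0
255,195,0
255,192,0
255,189,0
255,186,0
255,183,0
255,180,0
255,177,0
255,174,0
255,171,0
255,168,0
255,165,0
255,162,0
255,159,0
255,156,0
255,153,0
255,150,0
255,147,0
255,144,0
255,141,0
255,138,0
255,135,0
255,132,0
255,129,0
255,126,0
255,123,0
255,120,0
255,117,0
255,114,0
255,111,0
255,108,0
255,105,0
255,102,0
255,99,0
255,96,0
255,93,0
255,90,0
255,87,0
255,84,0
255,81,0
255,78,0
255,75,0
255,72,0
255,69,0
255,66,0
255,63,0
255,60,0
255,57,0
255,54,0
255,51,0
255,48,0
255,45,0
255,42,0
255,39,0
255,36,0
255,33,0
255,30,0
255,27,0
255,24,0
255,21,0
255,18,0
255,15,0
255,12,0
255,9,0
255,6,0
255,3,0
255,0,0
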