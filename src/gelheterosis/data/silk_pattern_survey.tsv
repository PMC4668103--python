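spot_id	hybrid	stage	fold_change	pattern
270	Xun928xZong3	D12	2.2	A
277	Lx9801xZong3	D12	Y/N	+
80	Xun928xZong3	D8	Y/N	+
121	Lx9801xZong3	D8	Y/N	A
148	Xun928xZong3	D10	Y/N	+
194	Lx9801xZong3	D10	2.9	A
238	Xun928xZong3	D12	3.4	++
155	Xun928xZong3	D10	Y/N	A
239	Xun928xZong3	D12	4.7	A
257	Xun928xZong3	D12	2.5	A
137	Lx9801xZong3	D8	Y/N	+
284	Lx9801xZong3	D12	Y/N	A
289	Lx9801xZong3	D12	Y/N	-
163	Xun928xZong3	D10	16.5	A
171	Xun928xZong3	D10	Y/N	A
236	Xun928xZong3	D12	4.2	++
243	Xun928xZong3	D12	6.1	+
89	Xun928xZong3	D8	Y/N	+-
118	Lx9801xZong3	D8	8.4	-
150	Xun928xZong3	D10	Y/N	A
272	Xun928xZong3	D12	Y/N	+
291	Lx9801xZong3	D12	3.9	A
79	Xun928xZong3	D8	Y/N	A
197	Lx9801xZong3	D10	Y/N	-
99	Xun928xZong3	D8	Y/N	A
117	Lx9801xZong3	D8	Y/N	+
122	Lx9801xZong3	D8	Y/N	A
123	Lx9801xZong3	D8	6.8	A
159	Xun928xZong3	D10	4.8	A
200	Lx9801xZong3	D10	Y/N	A
201	Lx9801xZong3	D10	6.3	A
212	Lx9801xZong3	D10	10.1	++
241	Xun928xZong3	D12	Y/N	A
119	Lx9801xZong3	D8	Y/N	A
152	Xun928xZong3	D10	Y/N	A
231	Lx9801xZong3	D10	Y/N	A
202	Lx9801xZong3	D10	5.3	A
76	Xun928xZong3	D8	9.2	A
138	Lx9801xZong3	D8	12.9	A
188	Xun928xZong3	D10	18.8	A
224	Lx9801xZong3	D10	15.1	+
285	Lx9801xZong3	D12	Y/N	A
96	Xun928xZong3	D8	3.6	-
255	Xun928xZong3	D12	Y/N	-
275	Lx9801xZong3	D12	Y/N	+
127	Lx9801xZong3	D8	Y/N	+
216	Lx9801xZong3	D10	Y/N	+-
298	Lx9801xZong3	D12	Y/N	A
217	Lx9801xZong3	D10	Y/N	+
223	Lx9801xZong3	D10	Y/N	A
74	Xun928xZong3	D8	Y/N	A
140	Lx9801xZong3	D8	Y/N	A
190	Xun928xZong3	D10	Y/N	A
268	Xun928xZong3	D12	Y/N	A
287	Lx9801xZong3	D12	Y/N	A
104	Xun928xZong3	D8	Y/N	A
176	Xun928xZong3	D10	Y/N	A
211	Lx9801xZong3	D10	Y/N	++
247	Xun928xZong3	D12	Y/N	A
177	Xun928xZong3	D10	Y/N	A
232	Lx9801xZong3	D10	Y/N	+
173	Xun928xZong3	D10	Y/N	A
95	Xun928xZong3	D8	Y/N	A
149	Xun928xZong3	D10	4.0	+
105	Xun928xZong3	D8	Y/N	A
160	Xun928xZong3	D10	5.1	A
165	Xun928xZong3	D10	5.2	A
204	Lx9801xZong3	D10	Y/N	+
292	Lx9801xZong3	D12	Y/N	+
86	Xun928xZong3	D8	Y/N	A
120	Lx9801xZong3	D8	Y/N	A
151	Xun928xZong3	D10	Y/N	A
220	Lx9801xZong3	D10	3.8	A
262	Xun928xZong3	D12	4.5	A
283	Lx9801xZong3	D12	Y/N	+-
164	Xun928xZong3	D10	Y/N	+
207	Lx9801xZong3	D10	Y/N	+
246	Xun928xZong3	D12	5.0	A
98	Xun928xZong3	D8	Y/N	A
244	Xun928xZong3	D12	Y/N	A
111	Xun928xZong3	D8	4.8	+-
115	Xun928xZong3	D8	Y/N	A
213	Lx9801xZong3	D10	Y/N	A
214	Lx9801xZong3	D10	Y/N	A
248	Xun928xZong3	D12	3.6	-
183	Xun928xZong3	D10	Y/N	A
110	Xun928xZong3	D8	Y/N	A
147	Xun928xZong3	D10	Y/N	-
87	Xun928xZong3	D8	Y/N	A
235	Xun928xZong3	D12	Y/N	A
88	Xun928xZong3	D8	Y/N	A
237	Xun928xZong3	D12	Y/N	+
199	Lx9801xZong3	D10	5.8	-
145	Xun928xZong3	D10	2.8	-
182	Xun928xZong3	D10	2.2	-
71	Xun928xZong3	D8	Y/N	A
124	Lx9801xZong3	D8	Y/N	-
67	Xun928xZong3	D8	3.0	A
106	Xun928xZong3	D8	Y/N	+
178	Xun928xZong3	D10	7.4	A
91	Xun928xZong3	D8	2.7	A
94	Xun928xZong3	D8	4.3	A
161	Xun928xZong3	D10	Y/N	A
72	Xun928xZong3	D8	Y/N	A
146	Xun928xZong3	D10	Y/N	A
112	Xun928xZong3	D8	3.4	A
251	Xun928xZong3	D12	Y/N	A
70	Xun928xZong3	D8	Y/N	A
258	Xun928xZong3	D12	Y/N	A
260	Xun928xZong3	D12	Y/N	A
279	Lx9801xZong3	D12	Y/N	A
252	Xun928xZong3	D12	3.4	A
229	Lx9801xZong3	D10	Y/N	A
288	Lx9801xZong3	D12	Y/N	-
267	Xun928xZong3	D12	Y/N	--
290	Lx9801xZong3	D12	Y/N	++
90	Xun928xZong3	D8	3.8	A
198	Lx9801xZong3	D10	Y/N	-
281	Lx9801xZong3	D12	Y/N	+-
225	Lx9801xZong3	D10	Y/N	+
266	Xun928xZong3	D12	Y/N	+-
286	Lx9801xZong3	D12	Y/N	+
107	Xun928xZong3	D8	2.9	A
274	Lx9801xZong3	D12	Y/N	+-
168	Xun928xZong3	D10	4.0	A
299	Lx9801xZong3	D12	Y/N	-
193	Xun928xZong3	D10	2.4	-
263	Xun928xZong3	D12	Y/N	-
69	Xun928xZong3	D8	Y/N	A
254	Xun928xZong3	D12	Y/N	A
187	Xun928xZong3	D10	2.8	+
265	Xun928xZong3	D12	11.2	A
109	Xun928xZong3	D8	Y/N	A
126	Lx9801xZong3	D8	Y/N	A
128	Lx9801xZong3	D8	5.4	A
169	Xun928xZong3	D10	4.6	+
113	Xun928xZong3	D8	Y/N	A
114	Xun928xZong3	D8	Y/N	A
135	Lx9801xZong3	D8	Y/N	A
179	Xun928xZong3	D10	Y/N	+
180	Xun928xZong3	D10	Y/N	A
245	Xun928xZong3	D12	Y/N	A
108	Xun928xZong3	D8	4.0	A
81	Xun928xZong3	D8	Y/N	A
233	Xun928xZong3	D12	Y/N	A
189	Xun928xZong3	D10	Y/N	-
116	Lx9801xZong3	D8	Y/N	A
228	Lx9801xZong3	D10	Y/N	A
210	Lx9801xZong3	D10	5.4	++
219	Lx9801xZong3	D10	Y/N	A
221	Lx9801xZong3	D10	Y/N	A
282	Lx9801xZong3	D12	Y/N	A
157	Xun928xZong3	D10	7.3	A
174	Xun928xZong3	D10	Y/N	A
259	Xun928xZong3	D12	Y/N	A
278	Lx9801xZong3	D12	Y/N	+
166	Xun928xZong3	D10	3.8	++
186	Xun928xZong3	D10	Y/N	A
218	Lx9801xZong3	D10	3.5	-
73	Xun928xZong3	D8	Y/N	+-
75	Xun928xZong3	D8	3.5	+-
141	Lx9801xZong3	D8	Y/N	A
191	Xun928xZong3	D10	Y/N	A
226	Lx9801xZong3	D10	Y/N	+
280	Lx9801xZong3	D12	Y/N	A
139	Lx9801xZong3	D8	Y/N	-
132	Lx9801xZong3	D8	Y/N	A
103	Xun928xZong3	D8	Y/N	-
130	Lx9801xZong3	D8	Y/N	-
172	Xun928xZong3	D10	Y/N	-
234	Xun928xZong3	D12	Y/N	-
129	Lx9801xZong3	D8	Y/N	A
134	Lx9801xZong3	D8	Y/N	A
209	Lx9801xZong3	D10	Y/N	+
261	Xun928xZong3	D12	3.5	--
185	Xun928xZong3	D10	Y/N	A
153	Xun928xZong3	D10	2.4	+
85	Xun928xZong3	D8	Y/N	A
264	Xun928xZong3	D12	Y/N	+-
203	Lx9801xZong3	D10	Y/N	-
293	Lx9801xZong3	D12	Y/N	-
192	Xun928xZong3	D10	Y/N	-
215	Lx9801xZong3	D10	Y/N	++
68	Xun928xZong3	D8	Y/N	A
136	Lx9801xZong3	D8	Y/N	A
181	Xun928xZong3	D10	Y/N	A
256	Xun928xZong3	D12	Y/N	A
276	Lx9801xZong3	D12	Y/N	+
167	Xun928xZong3	D10	2.6	+
97	Xun928xZong3	D8	Y/N	+
125	Lx9801xZong3	D8	Y/N	+
205	Lx9801xZong3	D10	5.8	A
250	Xun928xZong3	D12	Y/N	-
206	Lx9801xZong3	D10	Y/N	-
230	Lx9801xZong3	D10	Y/N	+
92	Xun928xZong3	D8	Y/N	+
271	Xun928xZong3	D12	Y/N	+-
175	Xun928xZong3	D10	Y/N	A
142	Xun928xZong3	D10	4.3	+
143	Xun928xZong3	D10	4.9	+
170	Xun928xZong3	D10	Y/N	+
208	Lx9801xZong3	D10	Y/N	+
249	Xun928xZong3	D12	Y/N	A
82	Xun928xZong3	D8	Y/N	A
83	Xun928xZong3	D8	9.5	A
84	Xun928xZong3	D8	Y/N	+
154	Xun928xZong3	D10	Y/N	A
195	Lx9801xZong3	D10	Y/N	-
294	Lx9801xZong3	D12	Y/N	-
196	Lx9801xZong3	D10	Y/N	-
295	Lx9801xZong3	D12	Y/N	-
77	Xun928xZong3	D8	Y/N	A
78	Xun928xZong3	D8	Y/N	A
253	Xun928xZong3	D12	3.9	--
93	Xun928xZong3	D8	Y/N	A
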