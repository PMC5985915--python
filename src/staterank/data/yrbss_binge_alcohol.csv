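state,prevalence_pct,se_pct,published_rank
Alabama,16.5,0.9,27
Alaska,13.2,0.8,43
Arizona,19.2,1.1,10
Arkansas,18.2,0.9,15
California,14.0,1.7,40
Colorado,20.7,1.8,5
Connecticut,17.0,0.8,24
Delaware,17.2,0.6,23
Florida,15.4,0.4,33
Georgia,14.5,1.0,37
Hawaii,13.1,0.6,43
Idaho,17.1,1.0,23
Illinois,17.5,0.8,20
Indiana,16.6,1.1,27
Iowa,21.3,2.4,3
Kansas,17.0,0.9,24
Kentucky,18.6,0.8,13
Louisiana,20.5,1.5,6
Maine,12.8,0.4,44
Maryland,15.1,0.6,35
Massachusetts,17.8,0.7,18
Michigan,14.4,0.7,38
Mississippi,15.9,0.9,30
Missouri,20.0,1.1,7
Montana,21.7,0.5,2
Nebraska,14.3,0.8,38
Nevada,15.7,1.0,31
New Hampshire,17.8,0.8,18
New Jersey,20.8,1.4,5
New Mexico,17.2,0.7,22
New York,17.3,0.9,21
North Carolina,14.1,0.7,39
North Dakota,18.9,0.8,11
Ohio,18.0,1.3,16
Oklahoma,18.2,0.9,15
Pennsylvania,13.2,1.1,43
Rhode Island,14.4,0.9,38
South Carolina,15.2,1.0,34
South Dakota,16.7,1.0,26
Tennessee,16.1,0.8,30
Texas,20.5,0.9,5
Utah,7.1,0.7,47
Vermont,17.3,0.4,22
Virginia,13.0,0.7,44
West Virginia,19.5,0.8,9
Wisconsin,18.7,1.0,12
Wyoming,20.8,0.7,5
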